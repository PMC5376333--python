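"""Synthetic phylogenies, trait evolution, and specimen tables.

Everything the analysis pipeline consumes can be generated here with known
parameters: ultrametric Yule (pure-birth) trees, bivariate trait evolution
under lambda-transformed Brownian motion, and specimen-level measurement
tables shaped like a stranding-network dissection dataset (multiple
carcasses per species, multiplicative measurement noise, per-fold length
lists that include occasional sub-millimeter wall foldings to exercise the
cleaning rules).

All generators are pure functions of their configuration and seed.

The trait model used throughout: the predictor (log10 body length) and the
response deviate evolve jointly; the response is

    log10 y = intercept_true + slope_true * log10 x + deviation,

with the bivariate evolutionary rate matrix of (log10 x, log10 y)
constructed so that its standardized major axis has slope exactly
``slope_true`` — i.e. the allometric exponent is the quantity an RMA fit
estimates, at any evolutionary correlation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .treeio import PhyloTree, VCVMatrix, lambda_transform, parse_newick, vcv_matrix

__all__ = [
    "SimConfig",
    "sim_yule_tree",
    "sim_traits_lambda_bm",
    "sim_allometric_specimens",
    "make_fixture",
    "rate_matrix_for_slope",
]

# Synthetic cetacean-like binomials for fixture tip labels (clearly invented).
_GENERA = [
    "Delphinops", "Phocoenoides", "Stenelloida", "Kogiopsis", "Tursiomima",
    "Lagenoressa", "Grampidella", "Orcinella", "Mesoplodus", "Balaenoptila",
    "Ziphiomima",
]
_EPITHETS = [
    "simulata", "ficta", "synthetica", "exemplaris", "virtualis", "artifica",
    "generata", "numerica", "stochastica", "modelica", "parametrica",
    "replicata", "seminata", "fabricata", "imitata", "designata", "codata",
    "emulata", "derivata", "algorithmica",
]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def rate_matrix_for_slope(
    slope: float, var_x: float, corr: float
) -> np.ndarray:
    """Bivariate evolutionary rate matrix whose SMA slope equals ``slope``.

    R = [[var_x, corr * slope * var_x], [corr * slope * var_x,
    slope^2 * var_x]]: sqrt(R_yy / R_xx) = slope for any evolutionary
    correlation ``corr`` in (-1, 1), so the allometric exponent is exactly
    the RMA estimand.
    """
    if var_x <= 0:
        raise ValueError("var_x must be positive")
    if not -1.0 < corr < 1.0:
        raise ValueError("corr must be in (-1, 1)")
    c = corr * slope * var_x
    return np.array([[var_x, c], [c, slope**2 * var_x]])


@dataclass
class SimConfig:
    """Generating parameters for a full synthetic study dataset.

    Defaults emulate the dissection-study design: 20 species, 1-5 specimens
    per species, log10 body length (cm) spread matching a typical cetacean
    size range, vaginal length scaling with exponent 1.4 and cumulative
    fold length with exponent 2.17, moderate phylogenetic signal, and 5%
    multiplicative within-species measurement noise.
    """

    n_species: int = 20
    birth_rate: float = 1.0
    lambda_true: float = 0.7
    slope_true: float = 1.4            # vaginal length ~ body length exponent
    intercept_true: float = -2.2       # log10 cm at log10 BL(cm) = 0
    slope_vfl_true: float = 2.17       # cumulative fold length exponent
    intercept_vfl_true: float = -3.7   # log10 mm
    var_x: float = 0.09                # evolutionary variance of log10 BL
    corr_true: float = 0.66            # evolutionary correlation of each pair
    root_logbl: float = 2.5            # log10 cm (~316 cm)
    specimens_per_species: tuple[int, int] = (1, 5)
    within_species_cv: float = 0.05
    fold_count_range: tuple[int, int] = (1, 13)
    submm_fold_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")
        if self.within_species_cv < 0:
            raise ValueError("within_species_cv must be >= 0")

    def rate_matrix(self, slope: float | None = None) -> np.ndarray:
        return rate_matrix_for_slope(
            self.slope_true if slope is None else slope, self.var_x, self.corr_true
        )


def sim_yule_tree(n_species: int, birth_rate: float = 1.0, seed=None) -> PhyloTree:
    """Simulate an ultrametric pure-birth (Yule) tree with ``n_species`` tips.

    Starting from the root split (two lineages), each of k extant lineages
    splits at total rate ``birth_rate * k``; the process runs until the
    (n+1)-th birth would occur, so the expected root-to-tip depth is
    sum_{k=2..n} 1 / (birth_rate * k).
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    return _sim_yule_nodes(n_species, birth_rate, _rng(seed))


class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self) -> None:
        self.children: list["_Node"] = []
        self.length = 0.0
        self.label: str | None = None

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.12g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.12g}"


def _sim_yule_nodes(n_species: int, birth_rate: float, rng) -> PhyloTree:
    root = _Node()
    left, right = _Node(), _Node()
    root.children = [left, right]
    active = [(left, 0.0), (right, 0.0)]  # (node, birth time)
    t = 0.0
    while True:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        if k == n_species:
            break
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.length = t - born
        a, b = _Node(), _Node()
        node.children = [a, b]
        active.append((a, t))
        active.append((b, t))
    for j, (node, born) in enumerate(active):
        node.length = t - born
        node.label = f"t{j + 1}"
    inner = ",".join(c.newick() for c in root.children)
    return parse_newick(f"({inner});")


def sim_traits_lambda_bm(
    tree: PhyloTree,
    lambda_true: float,
    R_true: np.ndarray,
    root_state,
    seed=None,
) -> np.ndarray:
    """Draw correlated traits under lambda-transformed Brownian motion.

    The n x m tip trait matrix is matrix-normal with mean 1 root_state' and
    covariance R_true (x) C(lambda_true); sampled via Cholesky (or
    eigenvalue, for semidefinite R_true) factorizations of both matrices.
    Rows follow the tree's tip order.
    """
    R_true = np.atleast_2d(np.asarray(R_true, dtype=float))
    root_state = np.atleast_1d(np.asarray(root_state, dtype=float))
    m = R_true.shape[0]
    if R_true.shape != (m, m) or root_state.shape != (m,):
        raise ValueError("R_true must be m x m and root_state length m")
    eigvals, eigvecs = np.linalg.eigh(R_true)
    if eigvals.min() < -1e-10:
        raise ValueError("R_true must be positive semidefinite")
    Lr = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))
    C = lambda_transform(vcv_matrix(tree), lambda_true)
    Lc = np.linalg.cholesky(C.values)
    rng = _rng(seed)
    Z = rng.standard_normal((C.n, m))
    return root_state + Lc @ Z @ Lr.T


def _split_folds(total_mm: float, rng, fold_count_range, submm_prob) -> list[float]:
    """Split a cumulative fold length into individual fold lengths (mm).

    Fold lengths decrease-ish from a Dirichlet split; with probability
    ``submm_prob`` per fold a sub-millimeter wall folding (0.1-0.9 mm,
    excluded by the cleaning rules from counts) is appended on top.
    """
    lo, hi = fold_count_range
    # fold count limited by the total: every synthesized fold is >= 1 mm so
    # the split preserves the cumulative length through the cleaning rules
    hi_eff = max(lo, min(hi, int(total_mm / 2.5) + 1))
    k = int(rng.integers(lo, hi_eff + 1))
    while True:
        weights = rng.dirichlet(np.ones(k) * 2.0)
        if k == 1 or (total_mm * weights).min() >= 1.0:
            break
        k = max(1, k - 1)
    folds = sorted((total_mm * weights).tolist(), reverse=True)
    extras = [float(v) for v in rng.uniform(0.1, 0.9, size=rng.binomial(k, submm_prob))]
    return [round(f, 2) for f in folds + extras]


def sim_allometric_specimens(config: SimConfig, out_path=None):
    """Generate a specimen-level measurement table with known parameters.

    Species mean log10 body length and the two responses are drawn under
    the lambda-BM model (vaginal length with ``slope_true``, cumulative fold
    length with ``slope_vfl_true``, independent deviations given body
    length); back-transformed means are then observed on 1-5 specimens per
    species with multiplicative lognormal noise at ``within_species_cv``.
    Each specimen's cumulative fold length is split into a per-fold list
    that occasionally includes sub-millimeter foldings.

    Returns ``(tree, dataframe)``; when ``out_path`` is given the table is
    also written as CSV.
    """
    rng = _rng(config.seed)
    tree = sim_yule_tree(config.n_species, config.birth_rate,
                         seed=rng.integers(2**31))
    # Joint rate matrix for (log BL, log VL, log VFL): each response is
    # correlated rho with body length and the responses correlate only
    # through body length (rho^2), keeping every pairwise SMA slope at its
    # target exponent.
    rho, vx = config.corr_true, config.var_x
    b1, b2 = config.slope_true, config.slope_vfl_true
    sd = np.array([1.0, b1, b2]) * np.sqrt(vx)
    corr = np.array([
        [1.0, rho, rho],
        [rho, 1.0, rho**2],
        [rho, rho**2, 1.0],
    ])
    R3 = corr * np.outer(sd, sd)
    root = np.array([
        config.root_logbl,
        config.intercept_true + b1 * config.root_logbl,
        config.intercept_vfl_true + b2 * config.root_logbl,
    ])
    X = sim_traits_lambda_bm(tree, config.lambda_true, R3, root,
                             seed=rng.integers(2**31))
    log_bl, log_vl, log_vfl = X[:, 0], X[:, 1], X[:, 2]

    sigma = np.sqrt(np.log1p(config.within_species_cv**2))
    rows = []
    lo, hi = config.specimens_per_species
    species = tree.tips
    counts = rng.integers(lo, hi + 1, size=len(species))
    spec_no = 0
    for i, sp in enumerate(species):
        for _ in range(int(counts[i])):
            spec_no += 1
            noise = rng.standard_normal(3) * sigma
            bl = 10 ** log_bl[i] * np.exp(noise[0])
            vl = 10 ** log_vl[i] * np.exp(noise[1])
            # smallest recordable fold is 1 mm after rounding
            vfl = max(10 ** log_vfl[i] * np.exp(noise[2]), 1.0)
            folds = _split_folds(vfl, rng, config.fold_count_range,
                                 config.submm_fold_prob)
            rows.append({
                "specimen_id": f"SYN{spec_no:04d}",
                "species": sp,
                "body_length_cm": round(bl, 1),
                "vaginal_length_cm": round(vl, 2),
                "fold_lengths_mm": ";".join(f"{f:g}" for f in folds),
                "maturity": rng.choice(["mature", "immature", "unknown"],
                                       p=[0.6, 0.3, 0.1]),
                "location": "synthetic",
            })
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return tree, df


def _species_names(n: int, rng) -> list[str]:
    names = []
    i = 0
    while len(names) < n:
        genus = _GENERA[i % len(_GENERA)]
        epithet = _EPITHETS[(i // len(_GENERA) + i) % len(_EPITHETS)]
        name = f"{genus}_{epithet}"
        if name not in names:
            names.append(name)
        i += 1
    return names


def make_fixture(seed: int, out_dir) -> dict:
    """Write the packaged 20-species / 59-specimen synthetic study bundle.

    Produces ``tree.nwk`` (ultrametric, cetacean-like synthetic binomials),
    ``specimens.csv`` (59 rows, 1-5 specimens per species) and
    ``manifest.json`` recording every generating parameter and content
    digests, so any downstream result can be traced to this seed.  Output is
    byte-identical for a given seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=int(seed))
    tree, df = sim_allometric_specimens(config)

    # rename generic tip labels to synthetic binomials, deterministically
    rng = _rng(seed + 1)
    names = _species_names(config.n_species, rng)
    mapping = dict(zip(tree.tips, names))
    newick = tree.as_newick()
    for old, new in sorted(mapping.items(), key=lambda kv: -len(kv[0])):
        newick = newick.replace(old + ":", new + ":")
    tree = parse_newick(newick)
    df["species"] = df["species"].map(mapping)

    # trim or pad specimens to exactly 59 rows, keeping >= 1 per species
    target = 59
    while len(df) > target:
        per = df["species"].value_counts()
        victims = df[df["species"].isin(per[per > 1].index)]
        df = df.drop(victims.index[-1])
    while len(df) < target:
        extra = df.iloc[[int(rng.integers(len(df)))]].copy()
        extra["specimen_id"] = f"SYN9{len(df):03d}"
        df = pd.concat([df, extra], ignore_index=True)
    df = df.sort_values(["species", "specimen_id"]).reset_index(drop=True)

    tree_path = out_dir / "tree.nwk"
    table_path = out_dir / "specimens.csv"
    tree_path.write_text(tree.as_newick() + "\n")
    df.to_csv(table_path, index=False)

    manifest = {
        "generator": "phylorma.synthetic_data.make_fixture",
        "seed": int(seed),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_species": int(df["species"].nunique()),
        "n_specimens": int(len(df)),
        "digests": {
            "tree.nwk": hashlib.sha256(tree_path.read_bytes()).hexdigest(),
            "specimens.csv": hashlib.sha256(table_path.read_bytes()).hexdigest(),
        },
        "note": "fully synthetic dataset; species names are invented",
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
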