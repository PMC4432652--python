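"""Information-based matching of genomic features to dependency profiles.

A target profile t (e.g. mutation status of an oncogene across cell
lines) is scored against every essentiality profile x (depletion scores
of one shRNA or gene solution across the same lines) with a rescaled
normalized mutual information:

    H(t,x)   = -integral P(t,x) log P(t,x)              (joint entropy, nats)
    MI(t,x)  =  integral P(t,x) log[P(t,x) / (P(t)P(x))]
    NMI(t,x) =  MI(t,x) / H(t,x)
    RNMI(t,x)=  sign(rho(t,x)) * NMI(t,x) / NMI(t,t)

where rho is the Pearson correlation supplying directionality.  A
perfect match scores +1, a perfect anti-match -1, and a random pair ~0.
Densities come from Gaussian product-kernel estimates on a regular grid
with leave-one-out least-squares cross-validated bandwidths; a binary
target is treated as discrete, its joint built from class-prior-weighted
class-conditional 1-D kernel densities.  Significance comes from a
global permutation null with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .formats import GctMatrix

logger = logging.getLogger(__name__)

EPS = 1e-12  # density floor before logs
_SQRT2PI = math.sqrt(2.0 * math.pi)

BandwidthMethod = Literal["cv", "silverman"]


class DegenerateProfileError(ValueError):
    pass


class EntropyUnderflowError(ValueError):
    """Joint differential entropy <= 0; NMI's sign would be meaningless.

    Rank-transforming the profiles (``rank_transform=True``) spreads
    peaked distributions onto normal scores and restores H > 0.
    """


# ---------------------------------------------------------------------------
# Profiles


@dataclass
class TargetProfile:
    """Per-sample feature values (binary context or continuous signal)."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) != self.values.size:
            raise ValueError("sample_ids/values length mismatch")
        finite = np.isfinite(self.values)
        if finite.sum() < 8:
            raise DegenerateProfileError("fewer than 8 samples with finite values")
        if np.ptp(self.values[finite]) == 0:
            raise DegenerateProfileError("constant target profile")


@dataclass
class EssentialityProfile:
    feature_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# Bandwidths


def silverman_bandwidth(v: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9 min(sd, IQR/1.349) n^(-1/5)."""
    n = v.size
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise DegenerateProfileError("degenerate profile (zero variance)")
    q75, q25 = np.percentile(v, [75, 25])
    iqr = (q75 - q25) / 1.349
    scale = min(sd, iqr) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


_CV_LADDER = np.geomspace(0.25, 4.0, 13)


def cv_bandwidth(v: np.ndarray) -> float:
    """Leave-one-out least-squares CV over a multiplier ladder.

    The LSCV risk of a Gaussian KDE has the closed form

        R(h) = (1/n^2) sum_ij phi(d_ij; sqrt(2) h)
             - (2/(n(n-1))) sum_{i != j} phi(d_ij; h)

    evaluated over {0.25..4} x rule-of-thumb on a log grid, ties to the
    smaller bandwidth.  Falls back to the rule of thumb when CV is
    degenerate (non-finite risk everywhere).
    """
    h0 = silverman_bandwidth(v)
    n = v.size
    d2 = (v[:, None] - v[None, :]) ** 2
    best_h, best_r = None, np.inf
    for m in _CV_LADDER:
        h = m * h0
        term1 = np.exp(-d2 / (4 * h * h)).sum() / (n * n * 2 * h * math.sqrt(math.pi))
        off = np.exp(-d2 / (2 * h * h)).sum() - n
        term2 = 2.0 * off / (n * (n - 1) * h * _SQRT2PI)
        r = term1 - term2
        if np.isfinite(r) and r < best_r:
            best_h, best_r = h, r
    return best_h if best_h is not None else h0


def select_bandwidth(v: np.ndarray, method: BandwidthMethod = "cv") -> float:
    if method == "cv":
        return cv_bandwidth(v)
    if method == "silverman":
        return silverman_bandwidth(v)
    raise ValueError(f"unknown bandwidth method {method!r}")


# ---------------------------------------------------------------------------
# Density grids


@dataclass
class DensityGrid:
    """Joint and marginal densities of (t, x) evaluated on a regular grid.

    For a binary target, ``grid_t`` holds the two class values,
    ``dt`` is None and the t-coordinate is discrete: ``joint[c, j]`` is
    class prior x class-conditional density, and sums (x dx) to 1.
    """

    grid_t: np.ndarray
    grid_x: np.ndarray
    joint: np.ndarray
    marginal_t: np.ndarray
    marginal_x: np.ndarray
    bandwidths: tuple[float | None, float]
    dt: float | None
    dx: float
    discrete_t: bool

    @property
    def cell_area(self) -> float:
        return self.dx if self.discrete_t else self.dt * self.dx


def _kernel_matrix(grid: np.ndarray, v: np.ndarray, h: float) -> np.ndarray:
    """Gaussian kernel density contributions, shape (grid, points)."""
    z = (grid[:, None] - v[None, :]) / h
    return np.exp(-0.5 * z * z) / (h * _SQRT2PI)


def _grid_for(v: np.ndarray, h: float, size: int) -> np.ndarray:
    return np.linspace(v.min() - 3.0 * h, v.max() + 3.0 * h, size)


def is_binary(v: np.ndarray) -> bool:
    return np.unique(v).size == 2


def estimate_density(
    t: np.ndarray,
    x: np.ndarray,
    grid_size: int = 64,
    bandwidth: BandwidthMethod = "cv",
    discrete_t: bool | None = None,
) -> DensityGrid:
    """Estimate the joint density of (t, x) for entropy/MI integration.

    Continuous pairs use a product Gaussian kernel on a ``grid_size`` x
    ``grid_size`` grid spanning each variable's range +/- 3 bandwidths.
    With ``discrete_t`` (auto-detected for two-valued targets) the joint
    is built as class-prior-weighted per-class 1-D kernel densities of x.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size != x.size:
        raise ValueError("profiles not aligned")
    for name, v in (("target", t), ("essentiality", x)):
        if np.ptp(v) == 0:
            raise DegenerateProfileError(f"degenerate {name} profile (constant)")
    if discrete_t is None:
        discrete_t = is_binary(t)

    h_x = select_bandwidth(x, bandwidth)
    grid_x = _grid_for(x, h_x, grid_size)
    dx = grid_x[1] - grid_x[0]

    if discrete_t:
        classes = np.unique(t)
        priors = np.array([(t == c).mean() for c in classes])
        joint = np.empty((classes.size, grid_size))
        for ci, c in enumerate(classes):
            xc = x[t == c]
            if xc.size == 0:
                joint[ci] = 0.0
                continue
            f = _kernel_matrix(grid_x, xc, h_x).sum(axis=1) / xc.size
            mass = f.sum() * dx
            joint[ci] = priors[ci] * (f / mass if mass > 0 else f)
        marginal_x = joint.sum(axis=0)
        return DensityGrid(
            grid_t=classes, grid_x=grid_x, joint=joint,
            marginal_t=priors, marginal_x=marginal_x,
            bandwidths=(None, h_x), dt=None, dx=dx, discrete_t=True,
        )

    h_t = select_bandwidth(t, bandwidth)
    grid_t = _grid_for(t, h_t, grid_size)
    dt = grid_t[1] - grid_t[0]
    Kt = _kernel_matrix(grid_t, t, h_t)
    Kx = _kernel_matrix(grid_x, x, h_x)
    joint = Kt @ Kx.T / t.size
    mass = joint.sum() * dt * dx
    joint = joint / mass
    marginal_t = joint.sum(axis=1) * dx
    marginal_x = joint.sum(axis=0) * dt
    return DensityGrid(
        grid_t=grid_t, grid_x=grid_x, joint=joint,
        marginal_t=marginal_t, marginal_x=marginal_x,
        bandwidths=(h_t, h_x), dt=dt, dx=dx, discrete_t=False,
    )


def joint_entropy(g: DensityGrid) -> float:
    """Riemann sum of -P log P over grid cells (nats).

    Cells with density below the floor contribute nothing.
    """
    P = g.joint
    mask = P > EPS
    return float(-(P[mask] * np.log(P[mask])).sum() * g.cell_area)


def mutual_information(g: DensityGrid) -> float:
    """Riemann sum of P log[P / (P_t P_x)] (nats), clipped at 0."""
    P = g.joint
    prod = np.outer(g.marginal_t, g.marginal_x)
    mask = (P > EPS) & (prod > EPS)
    mi = (P[mask] * np.log(P[mask] / prod[mask])).sum() * g.cell_area
    return float(max(mi, 0.0))


# ---------------------------------------------------------------------------
# Scores


@dataclass(frozen=True)
class ParisScore:
    feature_id: str
    H: float
    MI: float
    NMI: float
    RNMI: float
    rho: float
    sign: int


def nmi(
    t: np.ndarray,
    x: np.ndarray,
    grid_size: int = 64,
    bandwidth: BandwidthMethod = "cv",
    discrete_t: bool | None = None,
) -> float:
    """Normalized mutual information MI/H from one shared density grid."""
    g = estimate_density(t, x, grid_size, bandwidth, discrete_t)
    H = joint_entropy(g)
    if H <= 0:
        raise EntropyUnderflowError(
            "joint entropy <= 0 on the grid; consider rank_transform"
        )
    return mutual_information(g) / H


def self_nmi(
    t: np.ndarray,
    grid_size: int = 64,
    bandwidth: BandwidthMethod = "cv",
    discrete_t: bool | None = None,
) -> float:
    """NMI(t, t), the rescaling denominator.

    For a binary target both coordinates are discrete and MI(t,t) equals
    the Shannon entropy of the class prior, hence NMI(t,t) = 1 exactly.
    """
    t = np.asarray(t, dtype=float)
    if discrete_t is None:
        discrete_t = is_binary(t)
    if discrete_t:
        return 1.0
    return nmi(t, t, grid_size, bandwidth, discrete_t=False)


def _sign(rho: float) -> int:
    if rho > 0:
        return 1
    if rho < 0:
        return -1
    return 0


def rnmi(
    t: np.ndarray,
    x: np.ndarray,
    grid_size: int = 64,
    bandwidth: BandwidthMethod = "cv",
    nmi_tt: float | None = None,
    feature_id: str = "",
    discrete_t: bool | None = None,
) -> ParisScore:
    """RNMI = sign(rho) * NMI(t,x) / NMI(t,t), clipped to [-1, 1]."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if discrete_t is None:
        discrete_t = is_binary(t)
    if nmi_tt is None:
        nmi_tt = self_nmi(t, grid_size, bandwidth, discrete_t)
    if nmi_tt <= 0:
        raise EntropyUnderflowError("self-score NMI(t,t) <= 0")
    g = estimate_density(t, x, grid_size, bandwidth, discrete_t)
    H = joint_entropy(g)
    if H <= 0:
        raise EntropyUnderflowError(
            "joint entropy <= 0 on the grid; consider rank_transform"
        )
    MI = mutual_information(g)
    NMI = MI / H
    rho = float(np.corrcoef(t, x)[0, 1])
    s = _sign(rho)
    score = float(np.clip(s * NMI / nmi_tt, -1.0, 1.0))
    return ParisScore(feature_id, H, MI, NMI, score, rho, s)


def rank_transform(v: np.ndarray) -> np.ndarray:
    """Normal-scores transform: ranks mapped through the normal quantile."""
    from scipy.stats import norm, rankdata

    r = rankdata(v, method="average")
    return norm.ppf(r / (v.size + 1))


def score_all(
    t: TargetProfile,
    matrix: GctMatrix,
    grid_size: int = 64,
    bandwidth: BandwidthMethod = "silverman",
    apply_rank_transform: bool = False,
) -> list[ParisScore]:
    """Score every matrix row against the target.

    Matrix columns are aligned to the target's samples; rows with missing
    values on the shared samples are dropped and logged.  The self-score
    NMI(t,t) is computed once and reused.

    Ranking across features defaults to the shared rule-of-thumb
    bandwidth: per-feature cross-validated bandwidths make the joint
    entropy in NMI's denominator fluctuate between identically
    distributed features, which reshuffles ranks with noise rather than
    signal.  Pass ``bandwidth="cv"`` to cross-validate per feature.
    """
    shared = [s for s in t.sample_ids if s in matrix.column_ids]
    if len(shared) < 8:
        raise ValueError(f"only {len(shared)} shared samples; need at least 8")
    tv = np.array([t.values[t.sample_ids.index(s)] for s in shared])
    sub = matrix.select_columns(shared)
    discrete = is_binary(tv)
    if apply_rank_transform and not discrete:
        tv = rank_transform(tv)
    nmi_tt = self_nmi(tv, grid_size, bandwidth, discrete)
    scores: list[ParisScore] = []
    n_dropped = 0
    for rid, row in zip(sub.row_ids, sub.values):
        if not np.isfinite(row).all():
            n_dropped += 1
            continue
        xv = rank_transform(row) if apply_rank_transform else row
        scores.append(
            rnmi(tv, xv, grid_size, bandwidth, nmi_tt, feature_id=rid, discrete_t=discrete)
        )
    if n_dropped:
        logger.info("dropped %d rows with missing values", n_dropped)
    return scores


# ---------------------------------------------------------------------------
# Permutation significance


@dataclass
class ParisResult:
    table: pd.DataFrame  # feature, H, MI, NMI, RNMI, rho, p, fdr, rank
    metadata: dict = field(default_factory=dict)


def _binary_null_scores(
    tv: np.ndarray,
    X: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    grid_size: int,
    bandwidth: BandwidthMethod,
) -> np.ndarray:
    """Vectorized permutation null for a binary target.

    Per essentiality row the kernel matrix over its own grid is fixed
    under permutation of t, so each permutation reduces to class sums.
    """
    classes = np.unique(tv)
    n = tv.size
    R = X.shape[0]
    g = grid_size
    E = np.empty((R, g, n))
    dxs = np.empty(R)
    for r in range(R):
        h = select_bandwidth(X[r], bandwidth)
        grid = _grid_for(X[r], h, g)
        dxs[r] = grid[1] - grid[0]
        E[r] = _kernel_matrix(grid, X[r], h)
    E_flat = E.reshape(R * g, n)
    E_sum = E_flat.sum(axis=1).reshape(R, g)
    Xc = X - X.mean(axis=1, keepdims=True)
    null = np.empty((n_perm, R))
    for p in range(n_perm):
        perm = rng.permutation(n)
        m = (tv[perm] == classes[1]).astype(float)
        n1 = m.sum()
        n0 = n - n1
        S1 = (E_flat @ m).reshape(R, g)
        f1 = S1 / n1
        f0 = (E_sum - S1) / n0
        # renormalize each class density on its truncated grid
        f1 /= (f1.sum(axis=1, keepdims=True) * dxs[:, None])
        f0 /= (f0.sum(axis=1, keepdims=True) * dxs[:, None])
        p1 = n1 / n
        p0 = n0 / n
        q1 = p1 * f1
        q0 = p0 * f0
        H = np.zeros(R)
        MI = np.zeros(R)
        mix = q0 + q1
        for q, f in ((q0, f0), (q1, f1)):
            mask = q > EPS
            ql = np.where(mask, q, 1.0)
            H -= (np.where(mask, q * np.log(ql), 0.0)).sum(axis=1) * dxs
            fr = np.where(mask & (mix > EPS), f / np.where(mix > EPS, mix, 1.0), 1.0)
            MI += (np.where(mask, q * np.log(fr), 0.0)).sum(axis=1) * dxs
        MI = np.clip(MI, 0.0, None)
        nmi_vals = MI / H
        rho_sign = np.sign(Xc @ (m - p1))
        null[p] = np.clip(rho_sign * nmi_vals, -1.0, 1.0)
    return null.ravel()


def _generic_null_scores(
    tv: np.ndarray,
    X: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    grid_size: int,
    bandwidth: BandwidthMethod,
    nmi_tt: float,
) -> np.ndarray:
    null = np.empty(n_perm * X.shape[0])
    k = 0
    for _ in range(n_perm):
        tp = tv[rng.permutation(tv.size)]
        for row in X:
            null[k] = rnmi(tp, row, grid_size, bandwidth, nmi_tt, discrete_t=False).RNMI
            k += 1
    return null


def permutation_significance(
    t: TargetProfile,
    matrix: GctMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    grid_size: int = 64,
    bandwidth: BandwidthMethod = "silverman",
    apply_rank_transform: bool = False,
    two_sided: bool = False,
    empirical_fdr: bool = False,
) -> ParisResult:
    """Global permutation null, nominal p-values, and FDR.

    The target values are shuffled ``n_perm`` times and re-scored against
    every row; all permuted scores pool into one global null.  A feature's
    nominal p compares its score against the null scores of its own sign
    family (matches and anti-matches are distinct discoveries):

        p = (1 + #{same-sign null at least as extreme}) / (1 + family size)

    ``two_sided=True`` compares |RNMI| against |null| instead.  FDR is
    Benjamini–Hochberg over nominal p-values; ``empirical_fdr=True`` adds
    the ratio-of-tail-rates estimate as an extra column.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    observed = score_all(t, matrix, grid_size, bandwidth, apply_rank_transform)
    ids = [s.feature_id for s in observed]
    shared = [s for s in t.sample_ids if s in matrix.column_ids]
    tv = np.array([t.values[t.sample_ids.index(s)] for s in shared])
    discrete = is_binary(tv)
    if apply_rank_transform and not discrete:
        tv = rank_transform(tv)
    sub = matrix.select_columns(shared).select_rows(ids)
    X = sub.values
    if apply_rank_transform:
        X = np.apply_along_axis(rank_transform, 1, X)

    rng = np.random.default_rng(seed)
    if discrete:
        null = _binary_null_scores(tv, X, n_perm, rng, grid_size, bandwidth)
    else:
        nmi_tt = self_nmi(tv, grid_size, bandwidth, discrete_t=False)
        null = _generic_null_scores(tv, X, n_perm, rng, grid_size, bandwidth, nmi_tt)

    obs = np.array([s.RNMI for s in observed])
    if two_sided:
        null_abs = np.sort(np.abs(null))
        n_null = null_abs.size
        exceed = n_null - np.searchsorted(null_abs, np.abs(obs), side="left")
        p = (1.0 + exceed) / (1.0 + n_null)
    else:
        null_pos = np.sort(null[null >= 0])
        null_neg = np.sort(null[null < 0])
        p = np.empty(obs.size)
        for i, s in enumerate(obs):
            if s >= 0:
                exceed = null_pos.size - np.searchsorted(null_pos, s, side="left")
                p[i] = (1.0 + exceed) / (1.0 + null_pos.size)
            else:
                exceed = np.searchsorted(null_neg, s, side="right")
                p[i] = (1.0 + exceed) / (1.0 + null_neg.size)
    fdr = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "feature": ids,
            "H": [s.H for s in observed],
            "MI": [s.MI for s in observed],
            "NMI": [s.NMI for s in observed],
            "RNMI": obs,
            "rho": [s.rho for s in observed],
            "p": p,
            "fdr": fdr,
        }
    )
    if empirical_fdr:
        n_null = null.size
        n_obs = obs.size
        emp = np.empty(n_obs)
        for i, s in enumerate(obs):
            if s >= 0:
                tail_null = (null >= s).mean()
                tail_obs = (obs >= s).mean()
            else:
                tail_null = (null <= s).mean()
                tail_obs = (obs <= s).mean()
            emp[i] = min(1.0, tail_null / tail_obs) if tail_obs > 0 else 1.0
        table["empirical_fdr"] = emp
    table = table.sort_values(["RNMI", "feature"], ascending=[False, True]).reset_index(
        drop=True
    )
    table["rank"] = np.arange(1, len(table) + 1)
    metadata = {
        "n_permutations": n_perm,
        "seed": seed,
        "bandwidth": bandwidth,
        "grid_size": grid_size,
        "two_sided": two_sided,
        "n_null_scores": int(null.size),
        "discrete_target": bool(discrete),
    }
    return ParisResult(table=table, metadata=metadata)
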