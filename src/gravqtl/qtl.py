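"""QTL mapping for function-valued gravitropism traits.

Implements the mapping machinery used on recombinant inbred line (RIL)
populations with two homozygous genotype classes: hidden-Markov genotype
probabilities on a centimorgan grid, single-QTL Haley-Knott (HK) regression
scans, genome-wide permutation thresholds, penalized-LOD stepwise multi-QTL
model selection, per-time-point trait maps (tQTL), curve-parameter maps
(pQTL), LOD-drop support intervals, and the linking/matching of tQTL tracks
to pQTL.

Genotypes are coded AA=0, BB=1, missing=-1.  HK regression uses the expected
dosage ``P(BB) - P(AA)`` in [-1, 1]; the reported additive effect is the OLS
coefficient on that dosage, i.e. half the difference between the two
homozygote means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA, BB, MISSING = 0, 1, -1

__all__ = [
    "GeneticMap",
    "Genotypes",
    "GenotypeProbabilities",
    "ScanResult",
    "QTLFit",
    "QTLModel",
    "TQTLTrack",
    "haldane",
    "calc_genoprob",
    "sim_geno",
    "scanone_hk",
    "permutation_threshold",
    "stepwise_qtl",
    "map_tqtl",
    "map_pqtl",
    "support_interval",
    "link_tqtl_over_time",
    "match_tqtl_pqtl",
]


def haldane(d_cM):
    """Map distance (cM) -> recombination fraction, no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Marker positions in cM, grouped by chromosome.

    ``table`` has columns ``marker``, ``chrom``, ``pos`` (cM) and optionally
    ``bp`` (physical anchor).  Positions must be non-decreasing within each
    chromosome and marker names unique genome-wide.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "pos"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dups = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicated marker names: {dups}")
        for chrom, sub in t.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos"].to_numpy(dtype=float)) < 0):
                raise ValueError(f"non-monotone cM positions on chromosome {chrom}")

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def positions(self, chrom) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos"].to_numpy(dtype=float)

    def markers(self, chrom) -> list[str]:
        return self.table.loc[self.table["chrom"] == chrom, "marker"].tolist()


@dataclass
class Genotypes:
    """Individuals x markers genotype calls for a two-state RIL population."""

    individuals: list[str]
    markers: list[str]
    calls: np.ndarray  # int8, AA=0 BB=1 missing=-1

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("calls shape does not match individuals x markers")
        bad = ~np.isin(self.calls, (AA, BB, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0 (AA), 1 (BB), -1 (missing)}")

    @property
    def n(self) -> int:
        return len(self.individuals)


@dataclass
class GenotypeProbabilities:
    """P(AA), P(BB) on a marker + pseudomarker grid, per chromosome.

    ``grid`` maps chromosome -> (positions cM, is_marker mask); ``probs`` maps
    chromosome -> array (n_individuals, n_positions, 2) with state order
    (AA, BB).  Each pair sums to 1.
    """

    individuals: list[str]
    grid: dict
    probs: dict
    step: float
    error_prob: float
    forward: dict | None = None  # filtered (alpha) probabilities, for sampling

    def chrom_pos(self) -> list[tuple]:
        """Flattened (chrom, pos) list over the whole grid, map order."""
        return [
            (chrom, float(p))
            for chrom in self.grid
            for p in self.grid[chrom][0]
        ]

    def dosages(self) -> np.ndarray:
        """n x total_positions matrix of P(BB) - P(AA)."""
        return np.concatenate(
            [self.probs[c][:, :, 1] - self.probs[c][:, :, 0] for c in self.grid],
            axis=1,
        )


@dataclass
class ScanResult:
    """Single-QTL LOD profile over the evaluation grid for one trait."""

    trait: str
    table: pd.DataFrame  # columns chrom, pos, lod
    threshold: float | None = None
    n_perm: int | None = None
    alpha: float | None = None

    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def peak(self) -> tuple:
        row = self.table.iloc[int(self.table["lod"].to_numpy().argmax())]
        return row["chrom"], float(row["pos"]), float(row["lod"])


@dataclass
class QTLFit:
    chrom: object
    pos: float
    effect: float
    se: float
    interval: tuple | None = None  # (cM_lo, cM_hi)
    profile: ScanResult | None = None


@dataclass
class QTLModel:
    """A selected additive multi-QTL model."""

    trait: str
    qtl: list
    lod: float
    plod: float
    penalty: float

    @property
    def n_qtl(self) -> int:
        return len(self.qtl)


@dataclass
class TQTLTrack:
    """A run of consecutive time points sharing a co-located significant QTL."""

    chrom: object
    times: list
    peaks: list
    frame_min: float
    matched_pqtl: list = field(default_factory=list)

    @property
    def onset(self) -> float:
        return float(self.times[0])

    @property
    def duration(self) -> float:
        return len(self.times) * self.frame_min


# ---------------------------------------------------------------------------
# Genotype probabilities (2-state forward-backward)
# ---------------------------------------------------------------------------

def _chrom_grid(positions: np.ndarray, step: float):
    """Marker positions plus pseudomarkers every ``step`` cM."""
    if step <= 0:
        grid = np.unique(positions)
    else:
        lo, hi = positions[0], positions[-1]
        grid = np.union1d(np.round(positions, 9), np.round(np.arange(lo, hi, step), 9))
        grid = np.append(grid[grid < hi], hi) if grid[-1] != hi else grid
    is_marker = np.isin(grid, np.round(positions, 9))
    return grid, is_marker


def calc_genoprob(
    genotypes: Genotypes,
    gmap: GeneticMap,
    step_cM: float = 1.0,
    error_prob: float = 0.002,
) -> GenotypeProbabilities:
    """Forward-backward genotype probabilities on a pseudomarker grid.

    Transitions use the Haldane map function on inter-position distances;
    emissions are 1 - error_prob for the observed call and error_prob for the
    other state; missing calls and pseudomarkers are uninformative.  An
    individual untyped on a whole chromosome gets 1/2 everywhere there.
    """
    if genotypes.markers != gmap.table["marker"].tolist():
        raise ValueError("genotype marker order does not match the map")
    eps = float(error_prob)
    n = genotypes.n
    grid, probs, alphas = {}, {}, {}
    col = 0
    for chrom in gmap.chromosomes:
        mpos = gmap.positions(chrom)
        nm = len(mpos)
        obs = genotypes.calls[:, col : col + nm]
        col += nm
        gpos, is_marker = _chrom_grid(mpos, step_cM)
        P = len(gpos)
        marker_idx = np.searchsorted(gpos, np.round(mpos, 9))

        # emissions, shape (n, P, 2)
        E = np.ones((n, P, 2))
        for j, gi in enumerate(marker_idx):
            typed = obs[:, j] != MISSING
            g = obs[typed, j]
            e = np.full((g.size, 2), eps)
            e[np.arange(g.size), g] = 1.0 - eps
            # markers may share a grid index only if duplicated at same cM
            E[typed, gi, :] *= e

        r = haldane(np.diff(gpos))
        # forward
        alpha = np.empty((n, P, 2))
        a = 0.5 * E[:, 0, :]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, 0, :] = a
        for p in range(1, P):
            stay, sw = 1.0 - r[p - 1], r[p - 1]
            a = np.stack(
                (a[:, 0] * stay + a[:, 1] * sw, a[:, 0] * sw + a[:, 1] * stay),
                axis=1,
            ) * E[:, p, :]
            a /= a.sum(axis=1, keepdims=True)
            alpha[:, p, :] = a
        # backward
        b = np.ones((n, 2))
        post = np.empty((n, P, 2))
        post[:, -1, :] = alpha[:, -1, :]
        for p in range(P - 2, -1, -1):
            stay, sw = 1.0 - r[p], r[p]
            be = b * E[:, p + 1, :]
            b = np.stack(
                (be[:, 0] * stay + be[:, 1] * sw, be[:, 0] * sw + be[:, 1] * stay),
                axis=1,
            )
            b /= b.sum(axis=1, keepdims=True)
            pp = alpha[:, p, :] * b
            post[:, p, :] = pp / pp.sum(axis=1, keepdims=True)
        grid[chrom] = (gpos, is_marker)
        probs[chrom] = post
        alphas[chrom] = alpha
    return GenotypeProbabilities(
        individuals=list(genotypes.individuals),
        grid=grid,
        probs=probs,
        step=float(step_cM),
        error_prob=eps,
        forward=alphas,
    )


def sim_geno(probs: GenotypeProbabilities, n_draws: int = 256, seed: int = 0) -> dict:
    """Joint genotype imputations by forward-filter backward-sampling.

    Uses the filtered (forward) probabilities stored by calc_genoprob:
    P(s_p | s_{p+1}, data) is proportional to alpha_p(s) * T(s -> s_{p+1}).
    Returns chromosome -> int8 array (n_draws, n_individuals, n_positions);
    marginal state frequencies across draws converge on the posteriors.
    """
    if probs.forward is None:
        raise ValueError("probabilities lack forward messages; rerun calc_genoprob")
    rng = np.random.default_rng(seed)
    out = {}
    for chrom, (gpos, _) in probs.grid.items():
        post = probs.probs[chrom]
        alpha = probs.forward[chrom]
        n, P, _ = post.shape
        r = haldane(np.diff(gpos))
        draws = np.empty((n_draws, n, P), dtype=np.int8)
        for d in range(n_draws):
            g = np.empty((n, P), dtype=np.int8)
            g[:, -1] = rng.random(n) < post[:, -1, 1]
            for p in range(P - 2, -1, -1):
                stay, sw = 1.0 - r[p], r[p]
                nxt = g[:, p + 1]
                w_bb = alpha[:, p, 1] * np.where(nxt == BB, stay, sw)
                w_aa = alpha[:, p, 0] * np.where(nxt == BB, sw, stay)
                g[:, p] = rng.random(n) < w_bb / (w_aa + w_bb)
            draws[d] = g
        out[chrom] = draws
    return out


# ---------------------------------------------------------------------------
# Haley-Knott scan
# ---------------------------------------------------------------------------

def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on the column space of C."""
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def _scan_lod(D: np.ndarray, Y: np.ndarray, C: np.ndarray | None = None) -> np.ndarray:
    """LOD matrix (positions x traits) for HK regression.

    D: n x M dosage matrix, Y: n x P phenotypes, C: n x c covariates
    (intercept added implicitly).  LOD = (n/2) log10(RSS0 / RSS1).
    """
    n = D.shape[0]
    ones = np.ones((n, 1))
    C = ones if C is None else np.column_stack([ones, C])
    Dr = _residualize(D, C)
    Yr = _residualize(Y, C)
    rss0 = np.sum(Yr**2, axis=0)  # (P,)
    dd = np.sum(Dr**2, axis=0)  # (M,)
    dy = Dr.T @ Yr  # (M, P)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = rss0[None, :] - np.where(dd[:, None] > 1e-12, dy**2 / np.where(dd[:, None] > 0, dd[:, None], 1.0), 0.0)
        # relative floor: a numerically perfect fit cannot be improved on,
        # so further terms gain no LOD
        rss1 = np.maximum(rss1, rss0[None, :] * 1e-15)
        lod = (n / 2.0) * np.log10(np.where(rss0[None, :] > 0, rss0[None, :] / rss1, 1.0))
    lod[~np.isfinite(lod)] = 0.0
    return np.maximum(lod, 0.0)


def _complete_cases(y: np.ndarray):
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    return y[keep], keep


def scanone_hk(probs: GenotypeProbabilities, phenotype, trait: str = "trait") -> ScanResult:
    """Single-QTL genome scan by Haley-Knott regression on expected dosages.

    Individuals with missing phenotype are dropped.  A zero-variance
    phenotype yields LOD = 0 everywhere.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != len(probs.individuals):
        raise ValueError("phenotype length does not match individuals")
    y, keep = _complete_cases(y)
    D = probs.dosages()[keep]
    if y.size < 3 or np.var(y) == 0.0:
        lod = np.zeros(D.shape[1])
    else:
        lod = _scan_lod(D, y[:, None])[:, 0]
    cp = probs.chrom_pos()
    table = pd.DataFrame(
        {"chrom": [c for c, _ in cp], "pos": [p for _, p in cp], "lod": lod}
    )
    return ScanResult(trait=trait, table=table)


def permutation_threshold(
    probs: GenotypeProbabilities,
    phenotype,
    n_perm: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold from a phenotype-shuffling null.

    The phenotype is permuted against the (fixed) genotypes ``n_perm`` times;
    the threshold is the empirical 1 - alpha quantile (linear interpolation,
    type 7) of the genome-wide maximum LOD.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable quantile")
    y = np.asarray(phenotype, dtype=float)
    y, keep = _complete_cases(y)
    D = probs.dosages()[keep]
    rng = np.random.default_rng(seed)
    Y = np.empty((y.size, n_perm))
    for k in range(n_perm):
        Y[:, k] = rng.permutation(y)
    maxima = _scan_lod(D, Y).max(axis=0)
    return float(np.quantile(maxima, 1.0 - alpha))


# ---------------------------------------------------------------------------
# Stepwise multi-QTL selection
# ---------------------------------------------------------------------------

def _model_lod(D: np.ndarray, y: np.ndarray, idx: list[int]) -> float:
    n = y.size
    ones = np.ones((n, 1))
    yr0 = y - y.mean()
    rss0 = float(yr0 @ yr0)
    if not idx:
        return 0.0
    X = np.column_stack([ones, D[:, idx]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss1 = max(float(resid @ resid), rss0 * 1e-15)
    return (n / 2.0) * np.log10(rss0 / rss1)


def _refine_positions(D, y, idx, order_key):
    """Coordinate-wise re-scan of each selected position, others fixed."""
    idx = list(idx)
    for _ in range(10):
        moved = False
        for j in range(len(idx)):
            others = idx[:j] + idx[j + 1 :]
            C = D[:, others] if others else None
            lod = _scan_lod(D, y[:, None], C)[:, 0]
            lod[others] = -np.inf
            best = _argmax_tiebreak(lod, order_key)
            if lod[best] > lod[idx[j]] + 1e-9 and best not in idx:
                idx[j] = best
                moved = True
        if not moved:
            break
    return idx


def _argmax_tiebreak(lod: np.ndarray, order_key) -> int:
    m = lod.max()
    cand = np.flatnonzero(lod >= m - 1e-12)
    return int(min(cand, key=lambda i: order_key[i]))


def stepwise_qtl(
    probs: GenotypeProbabilities,
    phenotype,
    penalty: float,
    max_qtl: int = 6,
    trait: str = "trait",
    drop: float = 1.5,
) -> QTLModel:
    """Forward/backward search for an additive multi-QTL model.

    Forward: repeatedly add the position maximizing the joint-model LOD,
    refining all positions by coordinate-wise re-scan after each addition,
    up to ``max_qtl``; then backward elimination.  Among all visited models
    (including the empty model, pLOD = 0) the one with maximal penalized LOD
    pLOD = LOD - k * penalty is returned, with effects, standard errors and
    ``drop``-LOD support intervals from profile re-scans.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    y = np.asarray(phenotype, dtype=float)
    y, keep = _complete_cases(y)
    D = probs.dosages()[keep]
    cp = probs.chrom_pos()
    order_key = {i: (str(c), p) for i, (c, p) in enumerate(cp)}
    visited = [[]]
    idx: list[int] = []
    if np.var(y) > 0:
        for _ in range(max_qtl):
            C = D[:, idx] if idx else None
            lod = _scan_lod(D, y[:, None], C)[:, 0]
            if idx:
                lod[idx] = -np.inf
            best = _argmax_tiebreak(lod, order_key)
            if not np.isfinite(lod[best]) or lod[best] <= 0:
                break
            idx = _refine_positions(D, y, idx + [best], order_key)
            visited.append(list(idx))
        # backward elimination from the largest model
        cur = list(idx)
        while len(cur) > 1:
            options = [[q for q in cur if q != r] for r in cur]
            lods = [_model_lod(D, y, o) for o in options]
            j = int(np.argmax(lods))
            cur = options[j]
            visited.append(list(cur))
    # pick max pLOD over visited models
    best_model, best_plod, best_lod = [], 0.0, 0.0
    for m in visited:
        lod = _model_lod(D, y, m)
        plod = lod - len(m) * penalty
        if plod > best_plod + 1e-12:
            best_model, best_plod, best_lod = m, plod, lod
    qtl_fits = _fit_model(D, y, best_model, cp, drop)
    return QTLModel(trait=trait, qtl=qtl_fits, lod=best_lod, plod=best_plod, penalty=penalty)


def _fit_model(D, y, idx, cp, drop=1.5) -> list[QTLFit]:
    if not idx:
        return []
    n = y.size
    X = np.column_stack([np.ones(n), D[:, idx]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(n - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    fits = []
    for j, i in enumerate(idx):
        chrom, pos = cp[i]
        others = [q for q in idx if q != i]
        C = D[:, others] if others else None
        lod = _scan_lod(D, y[:, None], C)[:, 0]
        table = pd.DataFrame(
            {"chrom": [c for c, _ in cp], "pos": [p for _, p in cp], "lod": lod}
        )
        prof = ScanResult(trait="profile", table=table)
        lo, hi = support_interval(prof, (chrom, pos), drop)[1:]
        fits.append(
            QTLFit(
                chrom=chrom,
                pos=pos,
                effect=float(coef[1 + j]),
                se=float(se[1 + j]),
                interval=(lo, hi),
                profile=prof,
            )
        )
    fits.sort(key=lambda q: (str(q.chrom), q.pos))
    return fits


def support_interval(scan: ScanResult, peak, drop: float = 1.5):
    """LOD-drop support interval around a peak on its chromosome.

    Takes the contiguous run of positions around the peak with
    LOD >= peak LOD - drop, expanded by one evaluated position on each side
    (clamped to the chromosome ends).  A flat profile returns the whole
    chromosome.
    """
    chrom, pos = peak[0], float(peak[1])
    sub = scan.table[scan.table["chrom"] == chrom].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no positions on chromosome {chrom}")
    pos_arr = sub["pos"].to_numpy(dtype=float)
    lod = sub["lod"].to_numpy(dtype=float)
    pk = int(np.argmin(np.abs(pos_arr - pos)))
    if np.ptp(lod) == 0.0:  # flat profile
        return chrom, float(pos_arr[0]), float(pos_arr[-1])
    cut = lod[pk] - drop
    lo = pk
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = pk
    while hi < len(lod) - 1 and lod[hi + 1] >= cut:
        hi += 1
    lo = max(lo - 1, 0)
    hi = min(hi + 1, len(lod) - 1)
    return chrom, float(pos_arr[lo]), float(pos_arr[hi])


# ---------------------------------------------------------------------------
# tQTL / pQTL maps
# ---------------------------------------------------------------------------

def map_tqtl(
    probs: GenotypeProbabilities,
    angles: pd.DataFrame,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    max_qtl: int = 6,
    max_missing_frac: float = 0.5,
):
    """Stepwise QTL models for the tip angle at every time point.

    ``angles`` is lines x time points (columns are times in minutes, rows
    aligned with the individuals of ``probs``).  Each time point is mapped
    independently: a genome-wide permutation threshold at ``alpha`` is the
    stepwise penalty.  Returns (scans, models, heatmap) where ``heatmap`` is
    positions x times holding the model-attributed profile LOD, zero where
    insignificant.
    """
    if angles.shape[0] != len(probs.individuals):
        raise ValueError("angle matrix rows must align with individuals")
    cp = probs.chrom_pos()
    times = list(angles.columns)
    heat = np.zeros((len(cp), len(times)))
    scans, models = {}, {}
    rng = np.random.default_rng(seed)
    for k, t in enumerate(times):
        y = angles[t].to_numpy(dtype=float)
        if np.mean(~np.isfinite(y)) > max_missing_frac:
            continue
        sub_seed = int(rng.integers(2**31 - 1))
        thr = permutation_threshold(probs, y, n_perm=n_perm, alpha=alpha, seed=sub_seed)
        scan = scanone_hk(probs, y, trait=f"t{t}")
        scan.threshold, scan.n_perm, scan.alpha = thr, n_perm, alpha
        model = stepwise_qtl(probs, y, penalty=thr, max_qtl=max_qtl, trait=f"t{t}")
        scans[t], models[t] = scan, model
        for q in model.qtl:
            prof = q.profile.table
            on_chrom = prof["chrom"].to_numpy() == q.chrom
            lod = prof["lod"].to_numpy(dtype=float)
            sig = on_chrom & (lod >= thr)
            heat[:, k] = np.where(sig, np.maximum(heat[:, k], lod), heat[:, k])
    heatmap = pd.DataFrame(
        heat,
        index=pd.MultiIndex.from_tuples(cp, names=["chrom", "pos"]),
        columns=times,
    )
    return scans, models, heatmap


def map_pqtl(
    probs: GenotypeProbabilities,
    params: pd.DataFrame,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    max_qtl: int = 6,
) -> dict:
    """Stepwise QTL model per fitted-curve parameter column.

    ``params`` is lines x parameters (e.g. lambda, mu, A, P, overshoot, I),
    rows aligned with the individuals of ``probs``.  All-missing columns are
    skipped.
    """
    if params.shape[0] != len(probs.individuals):
        raise ValueError("parameter table rows must align with individuals")
    models = {}
    rng = np.random.default_rng(seed)
    for name in params.columns:
        y = params[name].to_numpy(dtype=float)
        if not np.isfinite(y).any():
            continue
        sub_seed = int(rng.integers(2**31 - 1))
        thr = permutation_threshold(probs, y, n_perm=n_perm, alpha=alpha, seed=sub_seed)
        models[name] = stepwise_qtl(probs, y, penalty=thr, max_qtl=max_qtl, trait=str(name))
    return models


# ---------------------------------------------------------------------------
# tQTL tracks and matching with pQTL
# ---------------------------------------------------------------------------

def link_tqtl_over_time(
    models_by_time: dict,
    link_dist_cM: float = 10.0,
    frame_min: float = 3.0,
) -> list[TQTLTrack]:
    """Link per-time-point QTL into tracks of consecutive co-located peaks.

    A track is a maximal run of consecutive time points, each holding a
    significant QTL on the same chromosome whose peak is within
    ``link_dist_cM`` of the previous time point's peak.  Duration is
    run length x ``frame_min``.
    """
    times = sorted(models_by_time)
    open_tracks: list[TQTLTrack] = []
    done: list[TQTLTrack] = []
    prev_t = None
    for t in times:
        peaks = [(q.chrom, q.pos) for q in models_by_time[t].qtl]
        consecutive = prev_t is not None
        still_open = []
        used = [False] * len(peaks)
        for tr in open_tracks:
            ext = None
            if consecutive:
                cands = [
                    (abs(p - tr.peaks[-1]), i)
                    for i, (c, p) in enumerate(peaks)
                    if not used[i] and c == tr.chrom and abs(p - tr.peaks[-1]) <= link_dist_cM
                ]
                if cands:
                    ext = min(cands)[1]
            if ext is None:
                done.append(tr)
            else:
                used[ext] = True
                tr.times.append(t)
                tr.peaks.append(peaks[ext][1])
                still_open.append(tr)
        open_tracks = still_open
        for i, (c, p) in enumerate(peaks):
            if not used[i]:
                open_tracks.append(TQTLTrack(chrom=c, times=[t], peaks=[p], frame_min=frame_min))
        prev_t = t
    done.extend(open_tracks)
    done.sort(key=lambda tr: (tr.onset, str(tr.chrom)))
    return done


def match_tqtl_pqtl(
    tracks: list[TQTLTrack],
    pqtl_models: dict,
    match_dist_cM: float = 10.0,
):
    """Partition tQTL tracks into pQTL-matched and unmatched classes.

    A track matches a pQTL if they share a chromosome and the minimum over
    the track's per-time peaks of |track peak - pQTL peak| is within
    ``match_dist_cM``.  Returns (matched, unmatched, summary) where summary
    holds mean and SD (ddof=1) of the durations of each class in minutes.
    """
    pq = [
        (param, q.chrom, q.pos)
        for param, model in pqtl_models.items()
        for q in model.qtl
    ]
    matched, unmatched = [], []
    for tr in tracks:
        labels = [
            param
            for param, chrom, pos in pq
            if chrom == tr.chrom and min(abs(p - pos) for p in tr.peaks) <= match_dist_cM
        ]
        tr.matched_pqtl = sorted(set(labels))
        (matched if labels else unmatched).append(tr)

    def _stats(trs):
        if not trs:
            return {"n": 0, "mean_duration": float("nan"), "sd_duration": float("nan")}
        d = np.array([tr.duration for tr in trs], dtype=float)
        return {
            "n": len(trs),
            "mean_duration": float(d.mean()),
            "sd_duration": float(d.std(ddof=1)) if len(d) > 1 else float("nan"),
        }

    summary = {"matched": _stats(matched), "unmatched": _stats(unmatched)}
    return matched, unmatched, summary
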