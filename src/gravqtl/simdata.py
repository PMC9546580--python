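"""Synthetic data with recorded ground truth for every pipeline stage.

Generates: two-state RIL genotypes on a centimorgan marker grid under a
Markov recombination model (Haldane map function, no residual
heterozygosity — the map is treated as already intermating-expanded);
sigmoid tip-angle trajectories whose curve parameters carry additive QTL
effects plus between-line and per-time-point noise; proteome pairs with
planted one-to-one orthologs, within-species paralog decoys and designed
reciprocity-failure cases; and backlit root image stacks with known tip
angles.

Genotype coding at a QTL is x in {-1/2, +1/2} (AA, BB), so a planted
"effect" is the full between-homozygote difference in the target parameter.
The gravitropic overshoot is injected as a Gaussian bump added to the
sigmoid, centered at lambda + A/mu with width A/(2*mu) minutes — a modeling
choice of this generator, not a mechanistic claim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .curves import logistic, gompertz
from .phenotyping import TipAngleSeries
from .qtl import AA, BB, MISSING, GeneticMap, Genotypes, haldane

__all__ = [
    "SimulationScenario",
    "PlantedTruth",
    "SyntheticProteomes",
    "simulate_genetic_map",
    "simulate_ril_genotypes",
    "simulate_phenotypes",
    "simulate_proteomes",
    "simulate_root_image_series",
]

PARAM_NAMES = ("lambda", "mu", "A", "overshoot")

#: per-parameter between-line SDs a field scientist would call realistic for
#: a maize RIL panel (deg, deg/min, min, deg)
DEFAULT_LINE_SD = {"lambda": 3.0, "mu": 0.08, "A": 4.0, "overshoot": 1.5}


@dataclass
class SimulationScenario:
    """Study conditions for one simulated gravitropism experiment.

    Defaults emulate the maize assay: 3-min frames for 3 h (61 points),
    a logistic response rising to A = 60 deg with maximum slope
    mu = 0.7 deg/min after a lag of lambda = 20 min, tip-angle observation
    noise 3 deg per time point.
    """

    seed: int = 0
    n_individuals: int = 250
    chromosomes: list = field(default_factory=lambda: [(str(c), 100.0) for c in range(1, 11)])
    marker_spacing: float = 5.0
    qtl_effects: list = field(default_factory=list)  # (chrom, pos_cM, param, effect)
    baseline: tuple = (60.0, 0.7, 20.0, "logistic")  # (A, mu, lambda, model)
    overshoot_amp: float = 0.0
    line_sd: dict = field(default_factory=lambda: dict(DEFAULT_LINE_SD))
    obs_sd: float = 3.0
    times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 181.0, 3.0))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.marker_spacing <= 0:
            raise ValueError("marker spacing must be positive")
        if self.obs_sd < 0:
            raise ValueError("obs_sd must be non-negative")
        lengths = dict(self.chromosomes)
        for chrom, pos, param, _ in self.qtl_effects:
            if param not in PARAM_NAMES:
                raise ValueError(f"unknown target parameter {param!r}; use one of {PARAM_NAMES}")
            if chrom not in lengths or not (0.0 <= pos <= lengths[chrom]):
                raise ValueError(f"QTL position {chrom}@{pos} is off the map")
        if self.baseline[3] not in ("logistic", "gompertz"):
            raise ValueError("baseline model must be 'logistic' or 'gompertz'")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside every simulated dataset."""

    curve_params: pd.DataFrame | None = None  # per-individual true parameters
    qtl_effects: list = field(default_factory=list)
    ortholog_pairs: list = field(default_factory=list)  # (gene_a, gene_b)
    in_interval_pairs: list = field(default_factory=list)
    bbh_failures: list = field(default_factory=list)
    tip_angles: list = field(default_factory=list)  # per image frame
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        if self.curve_params is not None:
            d["curve_params"] = {
                "index": [str(i) for i in self.curve_params.index],
                "columns": list(self.curve_params.columns),
                "data": self.curve_params.to_numpy().tolist(),
            }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        cp = d.get("curve_params")
        if cp is not None:
            d["curve_params"] = pd.DataFrame(cp["data"], index=cp["index"], columns=cp["columns"])
        d["qtl_effects"] = [tuple(e) for e in d.get("qtl_effects", [])]
        d["ortholog_pairs"] = [tuple(p) for p in d.get("ortholog_pairs", [])]
        d["in_interval_pairs"] = [tuple(p) for p in d.get("in_interval_pairs", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# Genetic map and RIL genotypes
# ---------------------------------------------------------------------------

def simulate_genetic_map(chromosomes, marker_spacing: float) -> GeneticMap:
    """Evenly spaced marker grid: markers at 0, s, 2s, ... per chromosome."""
    if marker_spacing <= 0:
        raise ValueError("marker spacing must be positive")
    rows = []
    for chrom, length in chromosomes:
        if length / marker_spacing < 2:
            raise ValueError(
                f"chromosome {chrom}: spacing {marker_spacing} leaves fewer than 2 intervals"
            )
        positions = np.arange(0.0, length + marker_spacing / 2, marker_spacing)
        for i, pos in enumerate(positions):
            rows.append({"marker": f"c{chrom}m{i:03d}", "chrom": chrom, "pos": float(pos)})
    return GeneticMap(pd.DataFrame(rows))


def simulate_ril_genotypes(
    gmap: GeneticMap,
    n: int,
    seed: int = 0,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> Genotypes:
    """Two-state RIL genotypes under a Markov model along each chromosome.

    Chromosome start states are Bernoulli(1/2); the switch probability
    between adjacent markers at map distance d is the Haldane recombination
    fraction r(d).  Observed calls are then flipped with ``error_rate`` and
    masked with ``missing_rate``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= error_rate <= 1 and 0 <= missing_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    blocks = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        r = haldane(np.diff(pos))
        g = np.empty((n, pos.size), dtype=np.int8)
        g[:, 0] = rng.random(n) < 0.5
        for j in range(1, pos.size):
            switch = rng.random(n) < r[j - 1]
            g[:, j] = np.where(switch, 1 - g[:, j - 1], g[:, j - 1])
        blocks.append(g)
    calls = np.concatenate(blocks, axis=1)
    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        calls = np.where(flip, 1 - calls, calls).astype(np.int8)
    if missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < missing_rate, MISSING, calls).astype(np.int8)
    return Genotypes(
        individuals=[f"RIL{i:04d}" for i in range(n)],
        markers=gmap.table["marker"].tolist(),
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Tip-angle trajectories with planted QTL effects
# ---------------------------------------------------------------------------

def _nearest_marker_index(gmap: GeneticMap, chrom, pos: float) -> int:
    t = gmap.table.reset_index(drop=True)
    on = t.index[t["chrom"] == chrom]
    if len(on) == 0:
        raise ValueError(f"no markers on chromosome {chrom}")
    sub = t.loc[on]
    return int(on[np.argmin(np.abs(sub["pos"].to_numpy(dtype=float) - pos))])


def _overshoot_bump(t, amp, A, mu, lam):
    center = lam + A / mu
    width = A / (2.0 * mu)
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def simulate_phenotypes(
    genotypes: Genotypes,
    scenario: SimulationScenario,
    gmap: GeneticMap,
):
    """Per-individual tip-angle trajectories carrying the planted QTL effects.

    Each individual's curve parameters are
    theta_i = baseline_theta + sum_j effect_j * x_ij + N(0, line_sd_theta^2)
    with x_ij = -1/2 (AA) or +1/2 (BB) at the marker nearest each planted
    QTL (missing calls contribute 0).  The trajectory is the baseline
    sigmoid at theta_i, plus a Gaussian overshoot bump when the overshoot
    parameter is nonzero, plus N(0, obs_sd^2) at every time point.

    Returns (series_list, PlantedTruth).
    """
    rng = np.random.default_rng(scenario.seed)
    n = genotypes.n
    t = scenario.times
    A0, mu0, lam0, model_name = scenario.baseline
    model = logistic if model_name == "logistic" else gompertz

    theta = {
        "A": np.full(n, float(A0)),
        "mu": np.full(n, float(mu0)),
        "lambda": np.full(n, float(lam0)),
        "overshoot": np.full(n, float(scenario.overshoot_amp)),
    }
    for chrom, pos, param, effect in scenario.qtl_effects:
        mi = _nearest_marker_index(gmap, chrom, pos)
        calls = genotypes.calls[:, mi]
        x = np.where(calls == MISSING, 0.0, np.where(calls == BB, 0.5, -0.5))
        theta[param] = theta[param] + effect * x
    for param in PARAM_NAMES:
        sd = float(scenario.line_sd.get(param, 0.0))
        if sd > 0:
            theta[param] = theta[param] + rng.normal(0.0, sd, size=n)
    theta["A"] = np.maximum(theta["A"], 1e-3)
    theta["mu"] = np.maximum(theta["mu"], 1e-3)

    series = []
    for i, ind in enumerate(genotypes.individuals):
        y = model(t, theta["A"][i], theta["mu"][i], theta["lambda"][i])
        if theta["overshoot"][i] != 0.0:
            y = y + _overshoot_bump(t, theta["overshoot"][i], theta["A"][i], theta["mu"][i], theta["lambda"][i])
        if scenario.obs_sd > 0:
            y = y + rng.normal(0.0, scenario.obs_sd, size=t.size)
        series.append(
            TipAngleSeries(seedling_id=ind, line=ind, times=t, angles=y, initial_subtracted=False)
        )
    truth = PlantedTruth(
        curve_params=pd.DataFrame(theta, index=list(genotypes.individuals)),
        qtl_effects=[tuple(e) for e in scenario.qtl_effects],
        extra={"baseline": list(scenario.baseline), "obs_sd": scenario.obs_sd},
    )
    return series, truth


# ---------------------------------------------------------------------------
# Proteome pairs with planted orthology
# ---------------------------------------------------------------------------

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SyntheticProteomes:
    """Two synthetic species: proteomes, gene annotations, QTL intervals."""

    proteins_a: dict
    proteins_b: dict
    genes_a: pd.DataFrame  # gene, chrom, start, end, strand
    genes_b: pd.DataFrame
    anchors_a: pd.DataFrame  # chrom, cM, bp
    anchors_b: pd.DataFrame
    intervals_a: pd.DataFrame  # label, chrom, cM_lo, cM_hi
    intervals_b: pd.DataFrame
    truth: PlantedTruth


def _mutate(seq: str, p: float, rng) -> str:
    s = np.array(list(seq))
    hit = rng.random(s.size) < p
    if hit.any():
        repl = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), size=int(hit.sum()))]
        same = repl == s[hit]
        while same.any():
            repl[same] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), size=int(same.sum()))]
            same = repl == s[hit]
        s[hit] = repl
    return "".join(s)


def _place_genes(ids, lengths_aa, rng, n_chrom=2):
    """Assign bp coordinates on ``n_chrom`` chromosomes, in id order."""
    rows = []
    cursors = {f"chr{c + 1}": 1 for c in range(n_chrom)}
    for k, (gid, la) in enumerate(zip(ids, lengths_aa)):
        chrom = f"chr{(k % n_chrom) + 1}"
        start = cursors[chrom] + int(rng.integers(2000, 10000))
        end = start + 3 * la + 2
        cursors[chrom] = end
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append({"gene": gid, "chrom": chrom, "start": start, "end": end, "strand": strand})
    return pd.DataFrame(rows)


def simulate_proteomes(
    n_genes: int = 60,
    n_intervals: int = 3,
    divergence: float = 0.2,
    paralog_spec: dict | None = None,
    seed: int = 0,
) -> SyntheticProteomes:
    """Two proteomes with planted one-to-one orthologs and paralog decoys.

    Each of ``n_genes`` ancestral proteins is mutated independently into a
    species-A and a species-B copy (per-site substitution probability
    ``divergence``/2 on each branch, so ortholog pairs diverge by about
    ``divergence``).  ``paralog_spec`` controls decoys:

    * ``n_paralogs`` within-species near-duplicates (divergence
      ``paralog_divergence`` from their template, which must exceed
      ``divergence``),
    * ``n_bbh_failures`` genes that get a cross-species-leaning decoy
      engineered to out-score the true partner in one direction, breaking
      reciprocity by design (recorded in the truth).

    The truth lists all planted pairs, the subset expected from a correct
    BBH-within-intervals run, and the designed failures.
    """
    spec = {"n_paralogs": 6, "paralog_divergence": 0.45, "n_bbh_failures": 2}
    spec.update(paralog_spec or {})
    if not (0.0 <= divergence < 1.0):
        raise ValueError("divergence must lie in [0, 1)")
    if spec["n_paralogs"] > 0 and spec["paralog_divergence"] <= divergence:
        raise ValueError("paralog divergence must exceed ortholog divergence")
    rng = np.random.default_rng(seed)

    prot_a, prot_b = {}, {}
    pairs = []
    for i in range(n_genes):
        length = int(rng.integers(90, 220))
        anc = "".join(AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), size=length)])
        ga, gb = f"GA{i:04d}", f"GB{i:04d}"
        prot_a[ga] = _mutate(anc, divergence / 2, rng)
        prot_b[gb] = _mutate(anc, divergence / 2, rng)
        pairs.append((ga, gb))

    # within-species paralog decoys (near-duplicates of existing genes)
    par_targets = rng.choice(n_genes, size=min(spec["n_paralogs"], n_genes), replace=False)
    for j, i in enumerate(par_targets):
        src, prot = (prot_a, "A") if j % 2 == 0 else (prot_b, "B")
        gid = f"G{prot}P{i:04d}"
        src[gid] = _mutate(src[f"G{prot}{i:04d}"], spec["paralog_divergence"], rng)

    # designed BBH failures: a species-A decoy closer to the B gene than the
    # planted A partner, so best_hit(B -> A) lands on the decoy
    failures = []
    fail_idx = rng.choice(n_genes, size=min(spec["n_bbh_failures"], n_genes), replace=False)
    fail_idx = [i for i in fail_idx if i not in set(par_targets)]
    for i in fail_idx:
        ga, gb = f"GA{i:04d}", f"GB{i:04d}"
        decoy = f"GAD{i:04d}"
        prot_a[decoy] = _mutate(prot_b[gb], max(divergence / 8, 0.01), rng)
        failures.append((ga, gb, decoy))
    failed = {f[0] for f in failures}

    ids_a = sorted(prot_a)
    ids_b = sorted(prot_b)
    genes_a = _place_genes(ids_a, [len(prot_a[g]) for g in ids_a], rng)
    genes_b = _place_genes(ids_b, [len(prot_b[g]) for g in ids_b], rng)

    # linear cM<->bp anchors: 1 cM per Mb, anchors at both chromosome ends
    def _anchors(genes):
        rows = []
        for chrom, sub in genes.groupby("chrom"):
            span = int(sub["end"].max()) + 10000
            rows.append({"chrom": chrom, "cM": 0.0, "bp": 1})
            rows.append({"chrom": chrom, "cM": span / 1e6, "bp": span})
        return pd.DataFrame(rows)

    anchors_a, anchors_b = _anchors(genes_a), _anchors(genes_b)

    # intervals: per species, n_intervals cM windows that tile alternating
    # thirds of each chromosome so a planted pair can be in both, one, or
    # neither species' intervals
    def _intervals(genes, anchors, label_prefix):
        rows = []
        chroms = sorted(genes["chrom"].unique())
        for k in range(n_intervals):
            chrom = chroms[k % len(chroms)]
            top = float(anchors.loc[anchors["chrom"] == chrom, "cM"].max())
            lo = top * (k // len(chroms)) / max(1, n_intervals // len(chroms) + 1)
            width = top / (n_intervals + 1)
            rows.append(
                {
                    "label": f"{label_prefix}{chrom}-{k + 1}",
                    "chrom": chrom,
                    "cM_lo": round(lo, 4),
                    "cM_hi": round(min(lo + width, top), 4),
                }
            )
        return pd.DataFrame(rows)

    intervals_a = _intervals(genes_a, anchors_a, "Aqtl-")
    intervals_b = _intervals(genes_b, anchors_b, "Bqtl-")

    def _in_intervals(genes, anchors, intervals):
        hits = set()
        for _, iv in intervals.iterrows():
            lo_bp = 1 + iv["cM_lo"] * 1e6
            hi_bp = 1 + iv["cM_hi"] * 1e6
            sub = genes[(genes["chrom"] == iv["chrom"]) & (genes["end"] >= lo_bp) & (genes["start"] <= hi_bp)]
            hits.update(sub["gene"])
        return hits

    in_a = _in_intervals(genes_a, anchors_a, intervals_a)
    in_b = _in_intervals(genes_b, anchors_b, intervals_b)
    expected = [
        (ga, gb)
        for ga, gb in pairs
        if ga in in_a and gb in in_b and ga not in failed
    ]
    # a designed-failure decoy is itself the reciprocal best partner of the
    # species-B gene, so a correct BBH run reports (decoy, gb) when both
    # fall inside intervals
    expected += [
        (decoy, gb)
        for ga, gb, decoy in failures
        if decoy in in_a and gb in in_b
    ]
    truth = PlantedTruth(
        ortholog_pairs=pairs,
        in_interval_pairs=expected,
        bbh_failures=[list(f) for f in failures],
        extra={"divergence": divergence, **spec},
    )
    return SyntheticProteomes(
        proteins_a=prot_a,
        proteins_b=prot_b,
        genes_a=genes_a,
        genes_b=genes_b,
        anchors_a=anchors_a,
        anchors_b=anchors_b,
        intervals_a=intervals_a,
        intervals_b=intervals_b,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Synthetic root images
# ---------------------------------------------------------------------------

def simulate_root_image_series(
    trajectory,
    px_per_mm: float = 10.0,
    width_px: int = 5,
    noise_sd: float = 0.0,
    n_frames: int | None = None,
    height_px: int = 200,
    frame_width_px: int = 200,
    step_px: float = 16.0,
    seed: int = 0,
):
    """Backlit-style image stack of a root growing at prescribed tip angles.

    ``trajectory`` gives the tip angle (deg, 90 = straight down) for each
    frame.  The root is drawn as a thick smooth curve growing from a seed
    blob at the top of the frame; each frame extends the path by ``step_px``
    in the direction of that frame's angle, so the terminal tangent — and
    the recorded truth — is exactly the prescribed angle.  Additive Gaussian
    pixel noise with SD ``noise_sd`` is applied to the [0, 1] intensity.
    """
    from skimage.draw import disk

    if width_px <= 1:
        raise ValueError("root width must exceed 1 px")
    angles = np.asarray(
        trajectory.angles if hasattr(trajectory, "angles") else trajectory, dtype=float
    )
    if n_frames is not None:
        angles = angles[:n_frames]
    rng = np.random.default_rng(seed)
    seed_pt = np.array([12.0, 0.0])  # (row, col); col shifted below
    # short emergence segment straight down from the kernel
    path = [seed_pt, seed_pt + np.array([14.0, 0.0])]
    for ang in angles:
        rad = np.deg2rad(ang)
        stepv = np.array([np.sin(rad), np.cos(rad)]) * step_px  # (d_row, d_col), y down
        path.append(path[-1] + stepv)
    path = np.array(path)
    # size the canvas to the whole path so no frame is ever clipped
    margin = 4.0 * width_px + 10.0
    path[:, 1] += margin - path[:, 1].min()
    height_px = max(height_px, int(path[:, 0].max() + margin))
    frame_width_px = max(frame_width_px, int(path[:, 1].max() + margin))

    stack = np.empty((angles.size, height_px, frame_width_px), dtype=float)
    canvas = np.zeros((height_px, frame_width_px))
    radius = width_px / 2.0

    def _stamp_segment(a, b):
        # dense float sampling keeps the drawn tube on the exact path,
        # avoiding the angular bias of integer-rounded line endpoints
        npts = max(int(np.hypot(*(b - a)) / 0.4) + 1, 2)
        for u in np.linspace(0.0, 1.0, npts):
            r, c = a + u * (b - a)
            rr, cc = disk((r, c), radius, shape=canvas.shape)
            canvas[rr, cc] = 1.0

    rr, cc = disk((path[0][0], path[0][1]), 1.5 * width_px, shape=canvas.shape)
    canvas[rr, cc] = 1.0
    _stamp_segment(path[0], path[1])
    for k in range(angles.size):
        _stamp_segment(path[k + 1], path[k + 2])
        frame = canvas.copy()
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        stack[k] = frame
    truth = PlantedTruth(tip_angles=[float(a) for a in angles], extra={"px_per_mm": px_per_mm})
    return stack, truth
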