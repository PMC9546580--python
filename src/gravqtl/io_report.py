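"""Readers, writers, configuration and figure-style outputs.

File dialects:

* genotype+map CSV — row 1: ``id`` then marker names; row 2: blank then
  chromosome per marker; row 3: blank then cM position; subsequent rows:
  individual id then codes ``A``/``B``/``-``.  Unknown codes are read as
  missing and counted in the log.
* phenotype CSV — one row per seedling (or line mean): ``id``, ``line``,
  then wide angle columns ``t_<minutes>``.
* parameter CSV — line, model, A, mu, lambda, P, overshoot, I, RSS,
  converged.
* anchors TSV (chrom, cM, bp), intervals TSV (label, chrom, cM_lo, cM_hi),
  FASTA proteomes, minimal gene-level GFF3.

All cM/bp coordinates in files are 1-based inclusive; the GFF3 boundary is
the only place a half-open convention would bite and the reader documents
it.  The tQTL heatmap is rendered with blue intensity proportional to LOD,
white below threshold, dashed separators at chromosome boundaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .curves import ResponseParameters
from .phenotyping import TipAngleSeries
from .qtl import AA, BB, MISSING, GeneticMap, Genotypes, QTLModel, ScanResult

logger = logging.getLogger("gravqtl")

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "read_cross",
    "write_cross",
    "read_phenotypes",
    "write_phenotypes",
    "write_parameters",
    "read_parameters",
    "write_lod_profiles",
    "write_qtl_models",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_anchors",
    "read_intervals",
    "representative_proteins",
    "heatmap_rgba",
    "render_heatmap",
    "write_image_stack",
]

CODE_TO_INT = {"A": AA, "B": BB, "-": MISSING}
INT_TO_CODE = {AA: "A", BB: "B", MISSING: "-"}


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one pipeline run; every stochastic stage is seeded."""

    out_dir: str = "runs/run0"
    seed: int = 0
    n_individuals: int = 250
    times: list = field(default_factory=lambda: [0.0, 180.0, 3.0])  # start, stop, step
    n_perm: int = 200
    alpha: float = 0.05
    step_cM: float = 1.0
    max_qtl: int = 6
    link_dist_cM: float = 10.0
    match_dist_cM: float = 10.0
    inputs: dict = field(default_factory=dict)

    def time_grid(self) -> np.ndarray:
        start, stop, step = self.times
        return np.arange(start, stop + step / 2, step)


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _toml_value(v):
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def save_config(cfg: RunConfig, path) -> None:
    """Write the config as TOML, every default made explicit, and log it."""
    lines = []
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, dict):
            continue
        lines.append(f"{f.name} = {_toml_value(v)}")
    if cfg.inputs:
        lines.append("")
        lines.append("[inputs]")
        for k, v in cfg.inputs.items():
            lines.append(f"{k} = {_toml_value(v)}")
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    logger.info("run config:\n%s", text)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Genotype + map CSV
# ---------------------------------------------------------------------------

def write_cross(gmap: GeneticMap, genotypes: Genotypes, path) -> None:
    t = gmap.table
    with open(path, "w") as fh:
        fh.write("id," + ",".join(t["marker"]) + "\n")
        fh.write("," + ",".join(str(c) for c in t["chrom"]) + "\n")
        fh.write("," + ",".join(f"{p:g}" for p in t["pos"]) + "\n")
        for ind, row in zip(genotypes.individuals, genotypes.calls):
            fh.write(ind + "," + ",".join(INT_TO_CODE[int(g)] for g in row) + "\n")


def read_cross(path):
    """Read the 3-header-row genotype+map CSV; returns (GeneticMap, Genotypes).

    Duplicate marker names or non-monotone cM positions are rejected with
    the offending line/column; unknown genotype codes become missing with a
    logged count.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        chroms = fh.readline().rstrip("\n").split(",")[1:]
        pos = fh.readline().rstrip("\n").split(",")[1:]
        markers = header[1:]
        if len(set(markers)) != len(markers):
            dups = sorted({m for m in markers if markers.count(m) > 1})
            raise ValueError(f"line 1: duplicated marker names {dups}")
        try:
            pos_f = [float(p) for p in pos]
        except ValueError as e:
            raise ValueError(f"line 3: bad cM position ({e})") from None
        table = pd.DataFrame({"marker": markers, "chrom": chroms, "pos": pos_f})
        for chrom, sub in table.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos"].to_numpy()) < 0):
                raise ValueError(f"line 3: non-monotone cM positions on chromosome {chrom}")
        gmap = GeneticMap(table)
        individuals, rows = [], []
        unknown = 0
        for ln, line in enumerate(fh, start=4):
            cells = line.rstrip("\n").split(",")
            if len(cells) != len(markers) + 1:
                raise ValueError(f"line {ln}: expected {len(markers) + 1} columns, got {len(cells)}")
            individuals.append(cells[0])
            row = []
            for c in cells[1:]:
                if c not in CODE_TO_INT:
                    unknown += 1
                    row.append(MISSING)
                else:
                    row.append(CODE_TO_INT[c])
            rows.append(row)
    if unknown:
        logger.warning("read_cross: %d unknown genotype codes treated as missing", unknown)
    genotypes = Genotypes(individuals=individuals, markers=markers, calls=np.array(rows, dtype=np.int8))
    return gmap, genotypes


# ---------------------------------------------------------------------------
# Phenotype / parameter tables
# ---------------------------------------------------------------------------

def write_phenotypes(series_list: list, path) -> None:
    times = series_list[0].times
    cols = ["id", "line"] + [f"t_{t:g}" for t in times]
    rows = []
    for s in series_list:
        if not np.array_equal(s.times, times):
            raise ValueError("all series must share one time grid")
        rows.append([s.seedling_id, s.line] + list(s.angles))
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_phenotypes(path) -> list:
    df = pd.read_csv(path)
    tcols = [c for c in df.columns if c.startswith("t_")]
    times = np.array([float(c[2:]) for c in tcols])
    out = []
    for _, row in df.iterrows():
        out.append(
            TipAngleSeries(
                seedling_id=str(row["id"]),
                line=str(row["line"]),
                times=times,
                angles=row[tcols].to_numpy(dtype=float),
            )
        )
    return out


PARAM_COLUMNS = ["line", "model", "A", "mu", "lambda", "P", "overshoot", "I", "RSS", "converged"]


def write_parameters(params: dict, path) -> pd.DataFrame:
    """``params`` maps line -> ResponseParameters (or None for failed fits)."""
    rows = []
    for line, p in params.items():
        if p is None:
            rows.append([line, "", *[np.nan] * 7, False])
        else:
            rows.append([line, p.model, p.A, p.mu, p.lam, p.P, p.overshoot, p.I, p.rss, p.converged])
    df = pd.DataFrame(rows, columns=PARAM_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_parameters(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_lod_profiles(scans: dict, path) -> None:
    frames = []
    for label, scan in scans.items():
        df = scan.table.copy()
        df.insert(0, "trait", label)
        df["threshold"] = scan.threshold
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _model_dict(model: QTLModel) -> dict:
    return {
        "trait": model.trait,
        "lod": model.lod,
        "plod": model.plod,
        "penalty": model.penalty,
        "qtl": [
            {
                "chrom": str(q.chrom),
                "pos": q.pos,
                "effect": q.effect,
                "se": q.se,
                "interval": list(q.interval) if q.interval else None,
            }
            for q in model.qtl
        ],
    }


def write_qtl_models(models: dict, path, seeds: dict | None = None) -> None:
    payload = {str(k): _model_dict(m) for k, m in models.items()}
    if seeds:
        payload["_meta"] = {"seeds": seeds}
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# FASTA / GFF3 / TSV
# ---------------------------------------------------------------------------

def write_fasta(proteins: dict, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in proteins.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3_genes(genes: pd.DataFrame, path, source: str = "gravqtl") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID=gene:{g['gene']}"
            fh.write(
                f"{g['chrom']}\t{source}\tgene\t{int(g['start'])}\t{int(g['end'])}\t.\t{g['strand']}\t.\t{attrs}\n"
            )


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file (1-based inclusive, per the format)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID", "")
            gid = gid.split("gene:", 1)[-1]
            rows.append(
                {"gene": gid, "chrom": f[0], "start": int(f[3]), "end": int(f[4]), "strand": f[6]}
            )
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])


def read_anchors(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "cM", "bp"}.issubset(df.columns):
        raise ValueError("anchor TSV needs columns chrom, cM, bp")
    return df


def read_intervals(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"label", "chrom", "cM_lo", "cM_hi"}.issubset(df.columns):
        raise ValueError("interval TSV needs columns label, chrom, cM_lo, cM_hi")
    return df


def representative_proteins(proteins: dict, sep: str = ".") -> dict:
    """Collapse isoforms (ids like gene.1, gene.2) to the longest per gene."""
    best: dict = {}
    for pid, seq in proteins.items():
        gene = pid.rsplit(sep, 1)[0] if sep in pid else pid
        if gene not in best or len(seq) > len(best[gene][1]):
            best[gene] = (pid, seq)
    return {gene: seq for gene, (_, seq) in best.items()}


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def heatmap_rgba(matrix: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """LOD matrix -> RGBA: white below threshold, blue intensity above.

    Pure coordinate bookkeeping lives here so it can be checked directly;
    rendering adds axes and separators around this array.
    """
    m = np.asarray(matrix, dtype=float)
    if m.size == 0:
        raise ValueError("empty heatmap matrix")
    top = max(float(np.nanmax(m)), threshold, 1e-12)
    frac = np.clip(np.where(m > max(threshold, 0.0), m / top, 0.0), 0.0, 1.0)
    rgba = np.ones(m.shape + (4,))
    # fade white -> saturated blue
    rgba[..., 0] = 1.0 - 0.9 * frac
    rgba[..., 1] = 1.0 - 0.75 * frac
    rgba[..., 2] = 1.0 - 0.25 * frac
    return rgba


def render_heatmap(heatmap: pd.DataFrame, threshold: float, path=None, title: str = "tQTL map"):
    """Render the positions x times LOD heatmap in the style of a tQTL figure.

    ``heatmap`` carries a (chrom, pos) MultiIndex on rows and times (min) on
    columns.  x = time, y = cumulative cM; dashed lines mark chromosome
    boundaries; insignificant cells are white.
    """
    if heatmap.size == 0:
        raise ValueError("empty heatmap matrix")
    rgba = heatmap_rgba(heatmap.to_numpy(), threshold)
    times = [float(t) for t in heatmap.columns]
    chroms = heatmap.index.get_level_values("chrom")
    pos = heatmap.index.get_level_values("pos").to_numpy(dtype=float)
    # cumulative cM axis
    cum = np.zeros(len(pos))
    offset, boundaries = 0.0, []
    last = None
    for i, (c, p) in enumerate(zip(chroms, pos)):
        if c != last and last is not None:
            offset = cum[i - 1]
            boundaries.append(offset)
        cum[i] = offset + p
        last = c
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.imshow(
        rgba,
        aspect="auto",
        origin="upper",
        extent=(times[0], times[-1], cum[-1], 0.0),
        interpolation="nearest",
    )
    for b in boundaries:
        ax.axhline(b, color="0.4", linestyle="--", linewidth=0.7)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cumulative position (cM)")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def write_image_stack(stack: np.ndarray, out_dir, prefix: str = "frame") -> list:
    """Write a float [0, 1]-ish image stack as 8-bit PNG frames."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    lo, hi = float(stack.min()), float(stack.max())
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    for k, frame in enumerate(stack):
        p = out_dir / f"{prefix}_{k:04d}.png"
        iio.imwrite(p, ((frame - lo) * scale).astype(np.uint8))
        paths.append(p)
    return paths
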