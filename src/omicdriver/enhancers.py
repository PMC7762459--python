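"""Enhancer and chromatin-state analysis on windowed signal tracks.

Signal tracks are fixed-width (default 50 bp) non-overlapping windows in
0-based half-open coordinates, held as DataFrames with columns
``chrom, start, end, value``.  The stage covers quantile normalization
across tracks, blacklist/promoter exclusion, strong/weak enhancer
classification from H3K4me1 + H3K27ac marks, tumor-vs-normal differential
calls (gain/loss at a fold-change threshold), the 18-state chromatin
activity split, basal-plus-extension gene regulatory domains, grouped
expression comparisons, and the genome-vs-enhancer explanation of driver
expression changes.

All interval logic is 0-based half-open: adjacent intervals [a,b) and
[b,c) never overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["chrom", "start", "end", "value"]


def _check_track(track: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"track missing columns {missing}")
    return track


def _same_grid(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    return (len(a) == len(b)
            and (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all())


def quantile_normalize(tracks: list) -> list:
    """Quantile-normalize >= 2 signal tracks on an identical window grid.

    Each track's values are replaced by the mean of the order statistics
    across tracks at the matching rank; ties receive the average of the
    reference values at their tied ranks.  Output distributions are
    identical across tracks (sorted vectors equal to machine precision).
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    tracks = [_check_track(t) for t in tracks]
    for t in tracks[1:]:
        if not _same_grid(tracks[0], t):
            raise ValueError("tracks must share an identical window grid")
    values = np.column_stack([t["value"].to_numpy(float) for t in tracks])
    ref = np.sort(values, axis=0).mean(axis=1)
    n = len(ref)
    out = []
    for j, t in enumerate(tracks):
        ranks = stats.rankdata(values[:, j], method="average")
        newv = np.interp(ranks, np.arange(1, n + 1), ref)
        tt = t.copy()
        tt["value"] = newv
        out.append(tt)
    return out


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED4 (0-based half-open); malformed lines raise with the
    line number."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {i}: {line!r}") from exc
            if end < start:
                raise ValueError(f"malformed BED line {i}: end < start")
            name = parts[3] if len(parts) > 3 else ""
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _overlaps_any(track: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: window overlaps (>= 1 bp) any interval; half-open."""
    mask = np.zeros(len(track), dtype=bool)
    if intervals is None or len(intervals) == 0:
        return mask
    for chrom, sub in intervals.groupby("chrom"):
        sel = track["chrom"] == chrom
        if not sel.any():
            continue
        # merge intervals, then windows overlap iff an interval starts
        # before the window end and ends after the window start
        iv = sub.sort_values("start")[["start", "end"]].to_numpy()
        merged = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        ws = track.loc[sel, "start"].to_numpy()
        we = track.loc[sel, "end"].to_numpy()
        # candidate interval: the last one starting before the window end
        j = np.searchsorted(starts, we, side="left") - 1
        hit = (j >= 0) & (np.where(j >= 0, ends[np.clip(j, 0, None)], 0) > ws)
        mask[np.where(sel)[0]] = hit
    return mask


def exclude_regions(track: pd.DataFrame,
                    blacklist: pd.DataFrame | None = None,
                    promoters: pd.DataFrame | None = None) -> pd.DataFrame:
    """Drop windows overlapping (>= 1 bp) any blacklist/promoter interval."""
    _check_track(track)
    drop = _overlaps_any(track, blacklist) | _overlaps_any(track, promoters)
    return track.loc[~drop].reset_index(drop=True)


def mark_threshold(track: pd.DataFrame, quantile: float = 0.75) -> float:
    """'Mark present' threshold: the given quantile of nonzero values."""
    v = track["value"].to_numpy(float)
    nz = v[v > 0]
    if len(nz) == 0:
        return np.inf
    return float(np.quantile(nz, quantile))


def classify_enhancers(h3k4me1: pd.DataFrame, h3k27ac: pd.DataFrame,
                       k4_threshold: float | None = None,
                       k27_threshold: float | None = None) -> pd.DataFrame:
    """Per-window enhancer class from the two histone marks.

    Strong: both H3K4me1 and H3K27ac at or above their thresholds; weak:
    H3K4me1 only; none otherwise (H3K27ac alone is not an enhancer).
    Thresholds default to the top quartile of each track's nonzero values.
    Input tracks should already have promoters and blacklisted windows
    excluded.
    """
    _check_track(h3k4me1)
    _check_track(h3k27ac)
    if not _same_grid(h3k4me1, h3k27ac):
        raise ValueError("mark tracks must share the window grid")
    if k4_threshold is None:
        k4_threshold = mark_threshold(h3k4me1)
    if k27_threshold is None:
        k27_threshold = mark_threshold(h3k27ac)
    k4 = h3k4me1["value"].to_numpy(float) >= k4_threshold
    k27 = h3k27ac["value"].to_numpy(float) >= k27_threshold
    cls = np.where(k4 & k27, "strong", np.where(k4, "weak", "none"))
    out = h3k4me1[["chrom", "start", "end"]].copy()
    out["k4me1"] = h3k4me1["value"].to_numpy(float)
    out["k27ac"] = h3k27ac["value"].to_numpy(float)
    out["cls"] = cls
    return out


def enhancer_differential(tumor: pd.DataFrame, normal: pd.DataFrame,
                          fold: float = 2.0,
                          pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-window gain/loss/stable status at a fold-change threshold.

    gain if (tumor + eps) / (normal + eps) >= fold; loss symmetrically;
    inclusive at the boundary.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    _check_track(tumor)
    _check_track(normal)
    if not _same_grid(tumor, normal):
        raise ValueError("tumor and normal tracks must share the grid")
    t = tumor["value"].to_numpy(float) + pseudocount
    n = normal["value"].to_numpy(float) + pseudocount
    status = np.where(t / n >= fold, "gain",
                      np.where(n / t >= fold, "loss", "stable"))
    out = tumor[["chrom", "start", "end"]].copy()
    out["tumor"] = tumor["value"].to_numpy(float)
    out["normal"] = normal["value"].to_numpy(float)
    out["status"] = status
    return out


def merge_windows(calls: pd.DataFrame, by=("cls", "status")) -> pd.DataFrame:
    """Merge adjacent windows sharing the given label columns into regions."""
    by = [c for c in by if c in calls.columns]
    out_rows = []
    prev = None
    for row in calls.sort_values(["chrom", "start"]).itertuples(index=False):
        r = row._asdict()
        key = tuple(r[c] for c in by)
        if (prev is not None and prev["chrom"] == r["chrom"]
                and prev["end"] == r["start"]
                and tuple(prev[c] for c in by) == key):
            prev["end"] = r["end"]
        else:
            if prev is not None:
                out_rows.append(prev)
            prev = {"chrom": r["chrom"], "start": r["start"],
                    "end": r["end"], **{c: r[c] for c in by}}
    if prev is not None:
        out_rows.append(prev)
    return pd.DataFrame(out_rows, columns=["chrom", "start", "end", *by])


def call_enhancers(k4_tumor, k27_tumor, k4_normal, k27_normal,
                   fold: float = 2.0, pseudocount: float = 1.0,
                   k4_threshold=None, k27_threshold=None,
                   merge: bool = True) -> pd.DataFrame:
    """Combined per-region enhancer calls: class plus differential status.

    Class is taken per window as the stronger of the tumor and normal
    classifications (strong > weak > none) so a lost enhancer keeps the
    class it had in normal; status is the H3K4me1 tumor/normal fold-change
    call.  Adjacent windows with identical (class, status) merge into
    regions unless ``merge=False``.
    """
    ct = classify_enhancers(k4_tumor, k27_tumor, k4_threshold, k27_threshold)
    cn = classify_enhancers(k4_normal, k27_normal, k4_threshold,
                            k27_threshold)
    rank = {"none": 0, "weak": 1, "strong": 2}
    inv = {v: k for k, v in rank.items()}
    cls = np.array([inv[max(rank[a], rank[b])]
                    for a, b in zip(ct["cls"], cn["cls"])], dtype=object)
    diff = enhancer_differential(k4_tumor, k4_normal, fold=fold,
                                 pseudocount=pseudocount)
    calls = diff[["chrom", "start", "end", "tumor", "normal",
                  "status"]].copy()
    calls["cls"] = cls
    if not merge:
        return calls
    return merge_windows(calls, by=("cls", "status"))


ACTIVE_STATES = {f"E{i}" for i in range(1, 13)}
INACTIVE_STATES = {f"E{i}" for i in range(13, 19)}


def chromatin_activity(states: pd.DataFrame) -> pd.DataFrame:
    """Map 18-state chromatin labels (E1..E18) to active/inactive.

    E1-E12 are active, E13-E18 inactive; an unknown label raises.
    """
    labels = states["name"].astype(str)
    out = states.copy()
    activity = []
    for lab in labels:
        if lab in ACTIVE_STATES:
            activity.append("active")
        elif lab in INACTIVE_STATES:
            activity.append("inactive")
        else:
            raise ValueError(f"unknown chromatin state label {lab!r}")
    out["activity"] = activity
    return out


def build_regulatory_domains(genes: pd.DataFrame,
                             basal_up: int = 5000,
                             basal_down: int = 1000,
                             extension: int = 20000) -> pd.DataFrame:
    """Basal-plus-extension gene regulatory domains.

    ``genes`` needs columns ``gene, chrom, tss, strand``.  The basal
    domain covers ``basal_up`` bp upstream to ``basal_down`` bp downstream
    of the TSS (strand-oriented); the extended domain grows outward from
    the basal edges by up to ``extension`` bp per side but is clipped at
    the nearest neighboring gene's basal domain (and at coordinate 0).
    Duplicate gene ids raise.
    """
    if genes["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in gene table")
    rows = []
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("tss").reset_index(drop=True)
        basal = []
        for r in sub.itertuples(index=False):
            if r.strand == "-":
                b = (max(0, r.tss - basal_down), r.tss + basal_up)
            else:
                b = (max(0, r.tss - basal_up), r.tss + basal_down)
            basal.append(b)
        for i, r in enumerate(sub.itertuples(index=False)):
            bs, be = basal[i]
            left = bs - extension
            right = be + extension
            # clip at neighboring basal domains
            for j in range(len(sub)):
                if j == i:
                    continue
                obs, obe = basal[j]
                if obe <= bs:          # neighbor to the left
                    left = max(left, obe)
                elif obs >= be:        # neighbor to the right
                    right = min(right, obs)
            left = max(0, min(left, bs))
            right = max(right, be)
            rows.append((r.gene, chrom, int(r.tss), r.strand,
                         int(bs), int(be), int(left), int(right)))
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand",
                                       "basal_start", "basal_end",
                                       "start", "end"])


def associate_regions_to_genes(regions: pd.DataFrame,
                               domains: pd.DataFrame) -> pd.DataFrame:
    """Region -> gene association: >= 1 bp overlap with the extended
    domain.  Returns one row per (region index, gene) pair."""
    pairs = []
    for chrom, dsub in domains.groupby("chrom"):
        rsub = regions[regions["chrom"] == chrom]
        if rsub.empty:
            continue
        for d in dsub.itertuples(index=False):
            hit = rsub[(rsub["start"] < d.end) & (rsub["end"] > d.start)]
            for ridx in hit.index:
                pairs.append((ridx, d.gene))
    return pd.DataFrame(pairs, columns=["region", "gene"])


def expression_by_enhancer_class(expr_tumor: pd.Series,
                                 expr_normal: pd.Series,
                                 region_gene: pd.DataFrame,
                                 calls: pd.DataFrame) -> pd.DataFrame:
    """Tumor-vs-normal expression tests per (enhancer class, status) group.

    The unit is the gene-region pair; each pair lands in exactly one
    (class in {strong, weak}) x (status in {gain, loss, stable}) group.
    Within a group the paired per-gene tumor and normal expression values
    are compared by the Wilcoxon signed-rank test.  Empty groups are
    skipped and logged.
    """
    merged = region_gene.merge(
        calls[["cls", "status"]], left_on="region", right_index=True)
    merged = merged[merged["cls"].isin(["strong", "weak"])]
    rows = []
    for (cls, status), grp in merged.groupby(["cls", "status"]):
        genes = [g for g in grp["gene"] if g in expr_tumor.index]
        if len(genes) < 3:
            logger.info("expression_by_enhancer_class: group (%s, %s) too "
                        "small, skipped", cls, status)
            continue
        t = expr_tumor.loc[genes].to_numpy(float)
        n = expr_normal.loc[genes].to_numpy(float)
        if np.allclose(t, n):
            p, w = 1.0, 0.0
        else:
            w, p = stats.wilcoxon(t, n)
        rows.append((cls, status, len(genes), float(np.mean(t - n)),
                     float(w), float(p)))
    return pd.DataFrame(rows, columns=["cls", "status", "n_pairs",
                                       "mean_shift", "statistic", "p"])


@dataclass
class ExplanationSummary:
    """Fractions of drivers whose expression change is accounted for."""
    n: int
    genome_fraction: float
    enhancer_fraction: float
    overlap_fraction: float


def explain_driver_expression(evidence: pd.DataFrame):
    """Genome- vs enhancer-based explanation of driver expression changes.

    ``evidence`` is indexed by driver id with columns ``direction``
    ('up'/'down'; anything else excludes the driver, logged) and boolean
    columns ``mutated, amplified, deleted, hypermethylated,
    enhancer_gain, enhancer_loss``.

    A down-regulated driver is genome-explained by mutation,
    hypermethylation or copy-number deletion, an up-regulated one by
    mutation or amplification; enhancer-explained means enhancer loss
    (down) or gain (up) within the driver's regulatory domain.  The two
    categories may overlap and are reported separately, never merged.

    Returns ``(records, summary)``.
    """
    known = evidence["direction"].isin(["up", "down"])
    dropped = evidence.index[~known]
    if len(dropped):
        logger.warning("explain_driver_expression: %d drivers without "
                       "direction excluded", len(dropped))
    ev = evidence.loc[known]
    down = ev["direction"] == "down"
    genome = np.where(
        down,
        ev["mutated"] | ev["hypermethylated"] | ev["deleted"],
        ev["mutated"] | ev["amplified"])
    enhancer = np.where(down, ev["enhancer_loss"], ev["enhancer_gain"])
    records = ev.copy()
    records["genome_explained"] = genome.astype(bool)
    records["enhancer_explained"] = enhancer.astype(bool)
    n = len(records)
    summary = ExplanationSummary(
        n=n,
        genome_fraction=float(records["genome_explained"].mean()) if n else 0.0,
        enhancer_fraction=float(records["enhancer_explained"].mean()) if n else 0.0,
        overlap_fraction=float((records["genome_explained"]
                                & records["enhancer_explained"]).mean()) if n else 0.0)
    return records, summary


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph into a signal track DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=TRACK_COLUMNS)
    return _check_track(df)


def write_bedgraph(track: pd.DataFrame, path) -> None:
    _check_track(track)[TRACK_COLUMNS].to_csv(path, sep="\t", header=False,
                                              index=False)
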