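"""Expression-inferred copy-number profiles for single cells.

Per-cell CNV estimates are obtained inferCNV-style: log2 library-normalized
expression is centered on a normal reference cell set, clipped, smoothed by a
genome-ordered moving average within each chromosome (edges use shrinking
windows), and median-centered per cell. Downstream helpers score single
genes, call malignant cells by CNV signal against the reference null, and
merge single-cell profiles into sample-level CNV events with per-group
frequency comparisons.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)


@dataclass
class CNVMatrix:
    """Cells x genes smoothed, reference-centered log2 relative expression.

    Columns follow genome order (chromosome, then position)."""

    values: np.ndarray
    cell_ids: pd.Index
    gene_order: pd.DataFrame  # genome-sorted annotation (gene_id index)
    window: int
    clip: float
    reference_cells: pd.Index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_order.index)


@dataclass
class CNVEventTable:
    """Sample-level CNV events: maximal runs of consecutive genes beyond the
    event threshold in the mean malignant profile of each sample."""

    events: pd.DataFrame  # sample, chromosome, start_index, end_index, direction, mean_value
    sample_profiles: pd.DataFrame  # samples x genes (genome order)
    event_threshold: float
    min_span: int
    excluded_samples: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _moving_average_block(A: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average of width ``window`` along axis 1 with shrinking
    windows at the edges (mean over the in-bounds part of the window)."""
    h = window // 2
    g = A.shape[1]
    cs = np.cumsum(A, axis=1)
    pos = np.arange(g)
    hi = np.minimum(pos + h, g - 1)
    lo = np.maximum(pos - h, 0)
    upper = cs[:, hi]
    lower = np.where(lo > 0, cs[:, np.maximum(lo - 1, 0)], 0.0)
    return (upper - lower) / (hi - lo + 1)


def infer_cnv(
    counts,
    annotation: pd.DataFrame,
    reference_cells,
    window: int = 101,
    clip: float = 3.0,
    target_sum: float = 1e4,
) -> CNVMatrix:
    """Infer per-cell CNV profiles from expression.

    Pipeline: log2(normalized + 1) -> subtract per-gene mean over reference
    cells -> clip to +-``clip`` -> per-chromosome centered moving average of
    width ``window`` (shrinking at edges) -> subtract per-cell median.
    Deterministic; genes are re-ordered to genome order internally, so gene
    input order never affects the result.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if clip <= 0:
        raise ValueError("clip must be positive")
    X = counts.X if hasattr(counts, "X") else counts
    cell_ids = counts.obs_names if hasattr(counts, "obs_names") else pd.RangeIndex(X.shape[0])
    cell_ids = pd.Index(cell_ids)
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)

    order = annotation.sort_values(["chromosome", "position"], kind="stable")
    col_idx = [annotation.index.get_loc(g) for g in order.index]
    X = X[:, col_idx]

    ref_idx = cell_ids.get_indexer(pd.Index(reference_cells))
    if len(ref_idx) == 0 or (ref_idx < 0).any():
        raise ValueError("reference cells empty or not present in the matrix")

    totals = X.sum(axis=1)
    zero_cells = totals == 0
    if zero_cells.any():
        logger.warning("%d all-zero cells flagged low-coverage in CNV inference",
                       int(zero_cells.sum()))
    totals[zero_cells] = 1.0
    logx = np.log2(X / totals[:, None] * target_sum + 1.0)

    ref_mean = logx[ref_idx].mean(axis=0)
    centered = np.clip(logx - ref_mean, -clip, clip)

    smoothed = np.empty_like(centered)
    chroms = order["chromosome"].to_numpy()
    for chrom in np.unique(chroms):
        block = np.flatnonzero(chroms == chrom)
        if window >= len(block):
            logger.info("window %d >= %d genes on chromosome %s: full-span window",
                        window, len(block), chrom)
        smoothed[:, block] = _moving_average_block(centered[:, block], window)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)

    return CNVMatrix(
        values=smoothed, cell_ids=cell_ids, gene_order=order,
        window=window, clip=clip, reference_cells=pd.Index(reference_cells),
    )


# ---------------------------------------------------------------------------
# gene-level scores
# ---------------------------------------------------------------------------

def gene_cnv_score(
    cnv: CNVMatrix,
    gene_id: str,
    origins=None,
    compare: tuple | None = None,
):
    """Per-cell CNV score of one gene = its column of the CNV matrix.

    With ``origins`` (per-cell labels) also returns per-origin mean scores;
    with ``compare=(a, b)`` additionally a two-sided rank-sum test between
    the two named origins. Returns (scores, summary dict).
    """
    if gene_id not in cnv.gene_order.index:
        near = difflib.get_close_matches(gene_id, list(cnv.gene_order.index), n=5)
        raise KeyError(f"gene {gene_id!r} not in annotation; nearest: {near}")
    col = cnv.gene_order.index.get_loc(gene_id)
    scores = pd.Series(cnv.values[:, col], index=cnv.cell_ids, name=gene_id)
    summary: dict = {}
    if origins is not None:
        origins = pd.Series(np.asarray(origins), index=cnv.cell_ids)
        summary["mean_by_origin"] = scores.groupby(origins).mean().to_dict()
        if compare is not None:
            from .clonal_dynamics import wilcoxon_rank_sum

            a, b = compare
            res = wilcoxon_rank_sum(
                scores[origins == a].to_numpy(), scores[origins == b].to_numpy()
            )
            summary["compare"] = {"pair": (a, b), "statistic": res.statistic, "p": res.p}
    return scores, summary


# ---------------------------------------------------------------------------
# malignancy calling
# ---------------------------------------------------------------------------

def cnv_signal(cnv: CNVMatrix) -> pd.Series:
    """Per-cell CNV signal = mean squared smoothed value."""
    return pd.Series((cnv.values**2).mean(axis=1), index=cnv.cell_ids, name="cnv_signal")


def call_malignant(
    cnv: CNVMatrix,
    reference_cells=None,
    quantile: float = 0.95,
    n_null: int = 1000,
    seed: int = 0,
):
    """Call cells malignant when their CNV signal exceeds the ``quantile`` of
    the reference cells' signals.

    With fewer than 20 reference cells the threshold is instead taken from a
    pooled permutation null (reference entries shuffled into synthetic
    profiles), with a warning. Returns (boolean Series, signal Series,
    threshold).
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    reference_cells = cnv.reference_cells if reference_cells is None else pd.Index(reference_cells)
    ref_idx = cnv.cell_ids.get_indexer(reference_cells)
    if len(ref_idx) == 0 or (ref_idx < 0).any():
        raise ValueError("reference cells empty or not present in the matrix")
    signal = cnv_signal(cnv)
    if len(ref_idx) < 20:
        logger.warning(
            "only %d reference cells; thresholding against a pooled permutation null",
            len(ref_idx),
        )
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA11]))
        pool = cnv.values[ref_idx].ravel()
        g = cnv.values.shape[1]
        null = (rng.choice(pool, size=(n_null, g)) ** 2).mean(axis=1)
        threshold = float(np.quantile(null, quantile))
    else:
        threshold = float(np.quantile(signal.iloc[ref_idx], quantile))
    calls = signal > threshold
    calls.name = "malignant_call"
    return calls, signal, threshold


# ---------------------------------------------------------------------------
# sample-level events
# ---------------------------------------------------------------------------

def _runs_above(mask: np.ndarray) -> list:
    """Maximal runs of True in a boolean vector as (start, end) half-open."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def merge_sample_cnv(
    cnv: CNVMatrix,
    sample_ids,
    malignant_calls,
    event_threshold: float = 0.25,
    min_span: int = 10,
    median_center_across_samples: bool = True,
) -> CNVEventTable:
    """Merge single-cell profiles to sample level and call CNV events.

    Sample profile = mean over its malignant cells; events = maximal runs of
    at least ``min_span`` consecutive genes (within a chromosome) whose mean
    value exceeds ``event_threshold`` in absolute value; the sign gives the
    direction. Samples without malignant cells are excluded with a log entry.

    ``median_center_across_samples`` (default on) subtracts the per-gene
    median over sample profiles before calling events: tumour-program vs
    reference expression differences reproduce across samples while genuine
    CNV segments are sample-specific, so the median removes the shared
    artifact. An alteration present in more than half of all samples would
    also be suppressed — disable the centering to look for such events.
    """
    sample_ids = pd.Series(np.asarray(sample_ids), index=cnv.cell_ids)
    calls = pd.Series(np.asarray(malignant_calls, dtype=bool), index=cnv.cell_ids)
    chroms = cnv.gene_order["chromosome"].to_numpy()
    profiles = {}
    excluded = []
    for s in pd.unique(sample_ids):
        mask = ((sample_ids == s) & calls).to_numpy()
        if not mask.any():
            logger.info("sample %s has no malignant cells; excluded from CNV events", s)
            excluded.append(s)
            continue
        profiles[s] = cnv.values[mask].mean(axis=0)
    prof_df = pd.DataFrame(profiles).T
    prof_df.columns = cnv.gene_order.index
    if median_center_across_samples and len(prof_df) >= 3:
        prof_df = prof_df - prof_df.median(axis=0)
        profiles = {s: prof_df.loc[s].to_numpy() for s in prof_df.index}

    rows = []
    for s, prof in profiles.items():
        for direction, mask in (
            ("gain", prof >= event_threshold),
            ("loss", prof <= -event_threshold),
        ):
            for chrom in np.unique(chroms):
                block = np.flatnonzero(chroms == chrom)
                for start, end in _runs_above(mask[block]):
                    if end - start >= min_span:
                        gs, ge = block[start], block[end - 1] + 1
                        rows.append(
                            dict(sample=s, chromosome=int(chrom), start_index=int(gs),
                                 end_index=int(ge), direction=direction,
                                 mean_value=float(prof[gs:ge].mean()))
                        )
    events = pd.DataFrame(
        rows, columns=["sample", "chromosome", "start_index", "end_index",
                       "direction", "mean_value"],
    )
    return CNVEventTable(
        events=events, sample_profiles=prof_df,
        event_threshold=event_threshold, min_span=min_span, excluded_samples=excluded,
    )


def _union_regions(events: pd.DataFrame, n_genes: int) -> list:
    """Merged regions (direction, start, end) covered by any sample's event."""
    regions = []
    for direction, grp in events.groupby("direction"):
        occ = np.zeros(n_genes, dtype=bool)
        for _, ev in grp.iterrows():
            occ[ev.start_index : ev.end_index] = True
        for start, end in _runs_above(occ):
            regions.append((direction, start, end))
    return sorted(regions, key=lambda r: (r[1], r[0]))


def event_frequencies(table: CNVEventTable, groups) -> pd.DataFrame:
    """Per-region event frequency (fraction of samples carrying an overlapping
    event of the same direction) for each group of samples."""
    groups = pd.Series(groups)
    regions = _union_regions(table.events, table.sample_profiles.shape[1])
    rows = []
    for direction, start, end in regions:
        row = dict(direction=direction, start_index=start, end_index=end)
        for gname, samples in groups.groupby(groups):
            members = samples.index
            n_hit = 0
            for s in members:
                hits = table.events[
                    (table.events["sample"] == s)
                    & (table.events["direction"] == direction)
                    & (table.events["start_index"] < end)
                    & (table.events["end_index"] > start)
                ]
                n_hit += int(len(hits) > 0)
            row[f"freq_{gname}"] = n_hit / max(len(members), 1)
            row[f"n_{gname}"] = len(members)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_event_frequencies(
    table: CNVEventTable, groups, group_a: str, group_b: str
) -> pd.DataFrame:
    """Fisher's exact test of event presence between two sample groups, per
    merged event region."""
    freq = event_frequencies(table, groups)
    ps = []
    for _, row in freq.iterrows():
        na, nb = int(row[f"n_{group_a}"]), int(row[f"n_{group_b}"])
        ka = int(round(row[f"freq_{group_a}"] * na))
        kb = int(round(row[f"freq_{group_b}"] * nb))
        _, p = fisher_exact([[ka, na - ka], [kb, nb - kb]])
        ps.append(p)
    freq["fisher_p"] = ps
    return freq
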