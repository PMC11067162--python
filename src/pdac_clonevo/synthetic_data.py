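"""Synthetic matched primary/metastatic PDAC scRNA-seq cohorts with planted ground truth.

Generates sparse gene x cell count matrices, genomic gene annotations and
per-patient clinical tables that emulate the statistical structure of a
matched primary / liver-metastasis PDAC cohort:

* negative-binomial counts mixing K latent malignant expression programs
  (cycling / classical / normal-like / basal-like by default) per cell;
* origin-structured clones carrying multi-gene CNV segments, with fewer
  clones in liver metastases (Lm) than in metastatic primaries (Pm1) than
  in non-metastatic primaries (Pm0);
* patient survival whose hazard jumps when the basal-like fraction of the
  primary tumour exceeds a planted threshold;
* immune-compartment fractions coupled to the basal-like fraction
  (negatively for cytotoxic T cells, positively for Tregs);
* one ligand-receptor pair co-expressed above background only in the Lm
  origin (ligand in malignant ductal cells, receptor in Tregs).

All randomness flows from a single master seed through
:class:`numpy.random.SeedSequence` spawning, so identical configs produce
byte-identical cohorts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

ORIGINS = ("Pn", "Pm0", "Pm1", "Lm")
#: tumour origins carrying malignant ductal cells
TUMOR_ORIGINS = ("Pm0", "Pm1", "Lm")
#: default names of the K=4 malignant programs, in program-index order
PROGRAM_NAMES = ("cycling", "classical", "normal_like", "basal_like")
IMMUNE_COMPARTMENTS = ("cytotoxic_t", "treg", "other_immune")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults mirror the study design
    (Pn: 5, Pm0: 6, Pm1: 15, Lm: 7 samples; 4 programs; 22% survival cutoff;
    clone counts Pm0=5 > Pm1=3 > Lm=1)."""

    n_genes: int = 2000
    n_chromosomes: int = 10
    n_cells_per_sample: int = 120
    samples_per_origin: dict = field(
        default_factory=lambda: {"Pn": 5, "Pm0": 6, "Pm1": 15, "Lm": 7}
    )
    k_programs: int = 4
    n_signature_genes_per_program: int = 50
    signature_boost: float = 12.0
    baseline_jitter_sd: float = 0.25
    dominant_usage: float = 0.8
    library_size_mean: float = 2500.0
    library_size_sd_log: float = 0.25
    nb_dispersion: float = 10.0
    malignant_cell_fraction: float = 0.5

    # clonal copy-number structure
    clone_counts: dict = field(
        default_factory=lambda: {"Pn": 0, "Pm0": 5, "Pm1": 3, "Lm": 1}
    )
    cnv_segments: list | None = None  # explicit (chrom, (start, end), fold) catalog
    n_truncal_segments: int = 2
    n_private_segments: int = 2
    segment_span: tuple = (60, 120)  # genes per segment
    gain_folds: tuple = (1.5, 2.0)
    loss_folds: tuple = (0.5,)

    # survival
    survival_cutoff: float = 0.22
    hazard_ratio_above_cutoff: float = 5.0
    base_hazard: float = math.log(2) / 9.7  # per month; median OS 9.7 months
    censoring_rate: float = 0.01
    horizon_months: float = 48.0

    # tumour micro-environment couplings (logit-scale coefficients on the
    # sample basal-like fraction)
    coupling_cytotoxic: float = -3.0
    coupling_treg: float = 3.0
    composition_noise_sd: float = 0.25

    # liver-metastasis-restricted ligand-receptor pair
    lm_only_lr_pair: tuple | None = None  # (ligand_gene_id, receptor_gene_id)
    lr_boost: float = 8.0

    # treatment response: recist = intercept + slope * basal_fraction + noise
    recist_slope: float = 150.0
    recist_intercept: float = -50.0
    recist_noise_sd: float = 20.0

    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_sample <= 0:
            raise ValueError("n_genes and n_cells_per_sample must be positive")
        if self.n_chromosomes <= 0 or self.n_genes < self.n_chromosomes:
            raise ValueError("need n_genes >= n_chromosomes >= 1")
        if not 0 < self.survival_cutoff < 1:
            raise ValueError("survival_cutoff must lie in (0, 1)")
        if self.hazard_ratio_above_cutoff <= 0 or self.base_hazard <= 0:
            raise ValueError("hazards must be positive")
        if any(f <= 0 for f in (*self.gain_folds, *self.loss_folds)):
            raise ValueError("fold changes must be positive")
        cc = self.clone_counts
        if not (cc.get("Lm", 0) <= cc.get("Pm1", 0) <= cc.get("Pm0", 0)):
            raise ValueError(
                "clone_counts must satisfy Lm <= Pm1 <= Pm0 "
                f"(got {cc})"
            )
        if any(v < 0 for v in cc.values()):
            raise ValueError("clone_counts must be non-negative")
        if self.samples_per_origin.get("Lm", 0) > self.samples_per_origin.get("Pm1", 0):
            raise ValueError("each Lm sample must pair with a Pm1 patient")
        if not 0 < self.malignant_cell_fraction < 1:
            raise ValueError("malignant_cell_fraction must lie in (0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic cohort."""

    true_spectra: pd.DataFrame  # programs x genes, rows sum to 1
    true_usages: pd.DataFrame  # malignant cells x programs, rows sum to 1
    true_program: pd.Series  # malignant cell -> dominant program index
    clone_of_cell: pd.Series  # malignant cell -> clone id
    segment_table: pd.DataFrame  # sample, clone, chrom, gene span, fold, truncal
    sample_basal_fraction: pd.Series
    patient_basal_fraction: pd.Series
    cutoff: float
    hazard_ratio: float
    coupling: dict
    lr_pair: tuple


@dataclass
class SyntheticCohort:
    """Counts (AnnData, cells x genes), gene annotation, clinical table, truth."""

    counts: ad.AnnData
    annotation: pd.DataFrame
    clinical: pd.DataFrame
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def generate_annotation(n_genes: int, n_chromosomes: int, seed: int = 0) -> pd.DataFrame:
    """Partition ``n_genes`` near-evenly across ``n_chromosomes`` with strictly
    increasing basepair-like positions within each chromosome.

    Returns a DataFrame with columns gene_id, chromosome, position,
    order_index (1-based rank within chromosome), indexed by gene_id.
    """
    if n_genes <= 0 or n_chromosomes <= 0:
        raise ValueError("n_genes and n_chromosomes must be positive")
    if n_genes < n_chromosomes:
        raise ValueError("need n_genes >= n_chromosomes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    sizes = np.full(n_chromosomes, n_genes // n_chromosomes, dtype=int)
    sizes[: n_genes % n_chromosomes] += 1
    rows = []
    gid = 0
    for chrom, size in enumerate(sizes, start=1):
        gaps = rng.integers(1_000, 100_000, size=size)
        positions = np.cumsum(gaps)
        for j in range(size):
            rows.append((f"g{gid:05d}", chrom, int(positions[j]), j + 1))
            gid += 1
    annot = pd.DataFrame(rows, columns=["gene_id", "chromosome", "position", "order_index"])
    return annot.set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance mean + mean^2/dispersion."""
    mean = np.maximum(mean, 1e-12)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _build_spectra(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """All program spectra (malignant K + normal ductal + 3 immune), rows sum 1.

    Signature genes are disjoint across programs; the last two genes are
    reserved for the ligand-receptor pair and never used as signatures.
    """
    n_programs = cfg.k_programs + 1 + len(IMMUNE_COMPARTMENTS)
    baseline = rng.lognormal(0.0, 1.0, size=cfg.n_genes)
    reserved = {cfg.n_genes - 2, cfg.n_genes - 1}
    candidates = np.array([g for g in range(cfg.n_genes) if g not in reserved])
    perm = rng.permutation(candidates)
    need = n_programs * cfg.n_signature_genes_per_program
    if need > len(candidates):
        raise ValueError("not enough genes for disjoint program signatures")
    spectra = np.empty((n_programs, cfg.n_genes))
    signatures = {}
    for k in range(n_programs):
        sig = perm[k * cfg.n_signature_genes_per_program : (k + 1) * cfg.n_signature_genes_per_program]
        signatures[k] = np.sort(sig)
        row = baseline * rng.lognormal(0.0, cfg.baseline_jitter_sd, size=cfg.n_genes)
        row[sig] *= cfg.signature_boost
        # reserved ligand/receptor genes stay at the shared, program-neutral
        # background so that outside Lm they are not differential between
        # cell classes
        row[list(reserved)] = baseline[list(reserved)]
        spectra[k] = row / row.sum()
    return spectra, signatures


def _sample_segments(
    cfg: SimulationConfig,
    annot: pd.DataFrame,
    rng: np.random.Generator,
    n_segments: int,
    occupied: list,
) -> list:
    """Sample ``n_segments`` non-overlapping (within a clone) gene spans.

    Returns a list of (chromosome, start_idx, end_idx, fold) with start/end as
    positions in genome order (half-open). ``occupied`` is extended in place.
    """
    chrom_bounds = {}
    order = np.asarray(annot["chromosome"])
    for chrom in np.unique(order):
        idx = np.flatnonzero(order == chrom)
        chrom_bounds[int(chrom)] = (int(idx[0]), int(idx[-1] + 1))
    segments = []
    attempts = 0
    while len(segments) < n_segments and attempts < 1000:
        attempts += 1
        chrom = int(rng.choice(list(chrom_bounds)))
        lo, hi = chrom_bounds[chrom]
        span = int(rng.integers(cfg.segment_span[0], cfg.segment_span[1] + 1))
        span = min(span, hi - lo)
        start = int(rng.integers(lo, hi - span + 1))
        end = start + span
        if any(s < end and start < e for (s, e) in occupied):
            continue
        if rng.random() < 0.5:
            fold = float(rng.choice(cfg.gain_folds))
        else:
            fold = float(rng.choice(cfg.loss_folds))
        occupied.append((start, end))
        segments.append((chrom, start, end, fold))
    if len(segments) < n_segments:
        logger.warning("could only place %d/%d CNV segments", len(segments), n_segments)
    return segments


def simulate_survival(
    basal_fractions: np.ndarray,
    cutoff: float,
    hazard_ratio: float,
    base_hazard: float,
    censoring_rate: float,
    horizon: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival whose hazard is multiplied by ``hazard_ratio`` for
    patients with basal fraction above ``cutoff``; independent exponential
    censoring plus an administrative horizon. Returns (times, events)."""
    basal_fractions = np.asarray(basal_fractions, dtype=float)
    hazard = base_hazard * np.where(basal_fractions > cutoff, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        t_cens = rng.exponential(1.0 / censoring_rate, size=len(hazard))
    else:
        t_cens = np.full(len(hazard), np.inf)
    t_cens = np.minimum(t_cens, horizon)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    times = np.maximum(times, 1e-3)  # strictly positive
    return times, events


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a full cohort with planted programs, clones, survival signal,
    immune couplings and an Lm-restricted ligand-receptor pair.

    Per-cell expected counts are ``library_size * (usages @ spectra)`` with
    CNV fold changes applied multiplicatively on the cell's clone segments;
    observed counts are negative binomial with shared dispersion.
    """
    cfg = config
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    (ss_annot, ss_spec, ss_design, ss_cells, ss_counts, ss_clin) = ss.spawn(6)
    rng_design = np.random.default_rng(ss_design)
    rng_cells = np.random.default_rng(ss_cells)
    rng_counts = np.random.default_rng(ss_counts)
    rng_clin = np.random.default_rng(ss_clin)

    annot = generate_annotation(cfg.n_genes, cfg.n_chromosomes, seed=cfg.seed)
    spectra, signatures = _build_spectra(cfg, np.random.default_rng(ss_spec))
    K = cfg.k_programs
    normal_prog = K
    immune_progs = {c: K + 1 + i for i, c in enumerate(IMMUNE_COMPARTMENTS)}
    basal_idx = K - 1  # last malignant program is basal-like by convention

    if cfg.lm_only_lr_pair is None:
        lig_gene = annot.index[cfg.n_genes - 2]
        rec_gene = annot.index[cfg.n_genes - 1]
    else:
        lig_gene, rec_gene = cfg.lm_only_lr_pair
        for g in (lig_gene, rec_gene):
            if g not in annot.index:
                raise ValueError(f"lr gene {g!r} not in annotation")
    lig_col = annot.index.get_loc(lig_gene)
    rec_col = annot.index.get_loc(rec_gene)

    # --- sample / patient design -----------------------------------------
    n_pm0 = cfg.samples_per_origin.get("Pm0", 0)
    n_pm1 = cfg.samples_per_origin.get("Pm1", 0)
    n_lm = cfg.samples_per_origin.get("Lm", 0)
    n_pn = cfg.samples_per_origin.get("Pn", 0)
    patients_pm0 = [f"P{i:02d}" for i in range(1, n_pm0 + 1)]
    patients_pm1 = [f"P{i:02d}" for i in range(n_pm0 + 1, n_pm0 + n_pm1 + 1)]
    samples = []  # (sample_id, origin, patient)
    for i, p in enumerate(patients_pm0):
        samples.append((f"{p}_Pm0", "Pm0", p))
    for i, p in enumerate(patients_pm1):
        samples.append((f"{p}_Pm1", "Pm1", p))
    for i in range(n_lm):
        p = patients_pm1[i]
        samples.append((f"{p}_Lm", "Lm", p))
    pn_hosts = (patients_pm1 + patients_pm0) or [f"P{i:02d}" for i in range(1, n_pn + 1)]
    for i in range(n_pn):
        p = pn_hosts[i % len(pn_hosts)]
        samples.append((f"{p}_Pn", "Pn", p))

    # per-sample malignant program mixing (flat Dirichlet: basal fraction
    # spreads across the planted 22% cutoff)
    mixing = {}
    for sid, origin, _ in samples:
        if origin in TUMOR_ORIGINS:
            mixing[sid] = rng_design.dirichlet(np.ones(K))

    # per-sample clone structure
    seg_rows = []
    clone_segments = {}  # (sample, clone) -> list of segments
    for sid, origin, _ in samples:
        n_clones = cfg.clone_counts.get(origin, 0)
        if origin not in TUMOR_ORIGINS or n_clones == 0:
            continue
        if cfg.cnv_segments is not None:
            catalog = [
                (int(c), int(s), int(e), float(f)) for (c, (s, e), f) in cfg.cnv_segments
            ]
            truncal = catalog
        else:
            occupied: list = []
            truncal = _sample_segments(cfg, annot, rng_design, cfg.n_truncal_segments, occupied)
        for j in range(n_clones):
            if cfg.cnv_segments is not None:
                private: list = []
            else:
                occ = [(s, e) for (_, s, e, _) in truncal]
                private = _sample_segments(cfg, annot, rng_design, cfg.n_private_segments, occ)
            segs = list(truncal) + private
            clone_segments[(sid, j)] = segs
            for chrom, s, e, fold in segs:
                seg_rows.append(
                    dict(sample=sid, clone=f"{sid}.c{j}", chromosome=chrom,
                         start_index=s, end_index=e, n_genes=e - s,
                         fold_change=fold, truncal=(chrom, s, e, fold) in truncal)
                )
    segment_table = pd.DataFrame(
        seg_rows,
        columns=["sample", "clone", "chromosome", "start_index", "end_index",
                 "n_genes", "fold_change", "truncal"],
    )

    # --- cells ------------------------------------------------------------
    obs_rows = []
    count_blocks = []
    usage_rows = {}
    clone_of_cell = {}
    sample_basal = {}
    n_cells = cfg.n_cells_per_sample
    for sid, origin, patient in samples:
        n_mal = int(round(cfg.malignant_cell_fraction * n_cells)) if origin in TUMOR_ORIGINS else 0
        n_duct_normal = 0 if origin in TUMOR_ORIGINS else int(round(cfg.malignant_cell_fraction * n_cells))
        n_immune = n_cells - n_mal - n_duct_normal

        # immune composition coupled to the sample basal-like mixing weight
        b_mix = mixing[sid][basal_idx] if origin in TUMOR_ORIGINS else 0.0
        logits = np.array(
            [
                math.log(0.35) + cfg.coupling_cytotoxic * b_mix,
                math.log(0.20) + cfg.coupling_treg * b_mix,
                math.log(0.45),
            ]
        ) + rng_cells.normal(0.0, cfg.composition_noise_sd, size=3)
        imm_frac = np.exp(logits) / np.exp(logits).sum()
        imm_counts = rng_cells.multinomial(n_immune, imm_frac)

        cell_usages = np.zeros((n_cells, spectra.shape[0]))
        compartments = []
        malignant = []
        cell_ids = [f"{sid}_c{i:04d}" for i in range(n_cells)]
        row = 0
        # malignant ductal cells
        if n_mal:
            dominant = rng_cells.choice(K, size=n_mal, p=mixing[sid])
            rest = rng_cells.dirichlet(np.ones(K - 1), size=n_mal) * (1 - cfg.dominant_usage)
            for i in range(n_mal):
                u = np.zeros(K)
                others = [k for k in range(K) if k != dominant[i]]
                u[others] = rest[i]
                u[dominant[i]] = cfg.dominant_usage
                cell_usages[row, :K] = u
                usage_rows[cell_ids[row]] = (u, int(dominant[i]))
                compartments.append("ductal")
                malignant.append(True)
                row += 1
            sample_basal[sid] = float(np.mean(dominant == basal_idx))
        for _ in range(n_duct_normal):
            cell_usages[row, normal_prog] = 1.0
            compartments.append("ductal")
            malignant.append(False)
            row += 1
        for comp, nc in zip(IMMUNE_COMPARTMENTS, imm_counts):
            for _ in range(int(nc)):
                cell_usages[row, immune_progs[comp]] = 1.0
                compartments.append(comp)
                malignant.append(False)
                row += 1

        # expected expression and CNV folds
        mean_profile = cell_usages @ spectra  # rows sum to 1
        fold = np.ones((n_cells, cfg.n_genes))
        n_clones = cfg.clone_counts.get(origin, 0)
        if n_mal and n_clones > 0:
            clone_assign = rng_cells.integers(0, n_clones, size=n_mal)
            for i in range(n_mal):
                j = int(clone_assign[i])
                clone_of_cell[cell_ids[i]] = f"{sid}.c{j}"
                for chrom, s, e, fc in clone_segments[(sid, j)]:
                    fold[i, s:e] *= fc
        elif n_mal:
            for i in range(n_mal):
                clone_of_cell[cell_ids[i]] = f"{sid}.c0"

        libsize = cfg.library_size_mean * rng_cells.lognormal(
            -0.5 * cfg.library_size_sd_log**2, cfg.library_size_sd_log, size=n_cells
        )
        mu = libsize[:, None] * mean_profile * fold
        # Lm-restricted ligand-receptor boost
        if origin == "Lm":
            mal_mask = np.array(malignant)
            treg_mask = np.array([c == "treg" for c in compartments])
            base_unit = libsize / cfg.n_genes
            mu[mal_mask, lig_col] += cfg.lr_boost * base_unit[mal_mask]
            mu[treg_mask, rec_col] += cfg.lr_boost * base_unit[treg_mask]

        counts = _nb_sample(rng_counts, mu, cfg.nb_dispersion)
        count_blocks.append(sp.csr_matrix(counts.astype(np.int32)))
        for i in range(n_cells):
            obs_rows.append(
                dict(cell_id=cell_ids[i], sample=sid, patient=patient, origin=origin,
                     compartment=compartments[i], malignant=malignant[i])
            )

    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    X = sp.vstack(count_blocks, format="csr")
    adata = ad.AnnData(X=X, obs=obs, var=annot.drop(columns=["gene_id"]))
    adata.var_names = annot.index

    # --- truth tables -----------------------------------------------------
    mal_cells = obs.index[obs["malignant"]]
    true_usages = pd.DataFrame(
        [usage_rows[c][0] for c in mal_cells],
        index=mal_cells,
        columns=[f"program_{k}" for k in range(K)],
    )
    true_program = pd.Series({c: usage_rows[c][1] for c in mal_cells}, name="program").loc[mal_cells]
    sample_basal_s = pd.Series(sample_basal, name="basal_fraction")

    # patient basal fraction from primary-tumour malignant cells (truth labels)
    prim = obs[obs["malignant"] & obs["origin"].isin(["Pm0", "Pm1"])]
    patient_basal = {}
    for patient, grp in prim.groupby("patient"):
        labels = true_program.loc[grp.index]
        patient_basal[patient] = float(np.mean(labels == basal_idx))
    patient_basal_s = pd.Series(patient_basal, name="basal_fraction").sort_index()

    # --- clinical table ---------------------------------------------------
    patients = sorted(patient_basal)
    bf = patient_basal_s.loc[patients].to_numpy()
    times, events = simulate_survival(
        bf, cfg.survival_cutoff, cfg.hazard_ratio_above_cutoff, cfg.base_hazard,
        cfg.censoring_rate, cfg.horizon_months, rng_clin,
    )
    clinical = pd.DataFrame(
        dict(
            patient=patients,
            os_months=np.round(times, 3),
            event=events,
            age=rng_clin.integers(45, 80, size=len(patients)),
            sex=rng_clin.choice(["F", "M"], size=len(patients), p=[0.62, 0.38]),
            grade=rng_clin.integers(1, 4, size=len(patients)),
            recist_pct_change=np.round(
                cfg.recist_intercept + cfg.recist_slope * bf
                + rng_clin.normal(0.0, cfg.recist_noise_sd, size=len(patients)),
                2,
            ),
            basal_fraction=bf,
        )
    ).set_index("patient", drop=False)

    truth = SyntheticTruth(
        true_spectra=pd.DataFrame(
            spectra[:K], index=[f"program_{k}" for k in range(K)], columns=annot.index
        ),
        true_usages=true_usages,
        true_program=true_program,
        clone_of_cell=pd.Series(clone_of_cell, name="clone").loc[mal_cells],
        segment_table=segment_table,
        sample_basal_fraction=sample_basal_s,
        patient_basal_fraction=patient_basal_s,
        cutoff=cfg.survival_cutoff,
        hazard_ratio=cfg.hazard_ratio_above_cutoff,
        coupling={"cytotoxic_t": cfg.coupling_cytotoxic, "treg": cfg.coupling_treg},
        lr_pair=(lig_gene, rec_gene),
    )
    return SyntheticCohort(counts=adata, annotation=annot, clinical=clinical, truth=truth)


# ---------------------------------------------------------------------------
# pseudobulk mixtures
# ---------------------------------------------------------------------------

def subtype_mean_profiles(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-program mean library-normalized expression over malignant cells
    using true program labels (genes x K, columns sum to 1)."""
    adata = cohort.counts
    labels = cohort.truth.true_program
    X = adata[labels.index].X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    norm = X / totals
    K = cohort.truth.true_spectra.shape[0]
    prof = np.zeros((adata.n_vars, K))
    for k in range(K):
        mask = (labels == k).to_numpy()
        if mask.any():
            prof[:, k] = norm[mask].mean(axis=0)
    cols = list(cohort.truth.true_spectra.index)
    return pd.DataFrame(prof, index=adata.var_names, columns=cols)


def make_pseudobulk(
    cohort: SyntheticCohort,
    weights: np.ndarray | pd.DataFrame,
    depth: float = 1e6,
    nb_dispersion: float | None = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk mixtures of the cohort's subtype mean profiles.

    Each bulk profile is ``depth * (profiles @ w)`` for a weight row ``w``
    summing to 1, with negative-binomial noise (``nb_dispersion=None`` gives
    the exact noiseless expectation). Returns (bulk genes x n_bulk, true
    fractions n_bulk x K).
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2:
        raise ValueError("weights must be an (n_bulk, K) array")
    if not np.allclose(W.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each weights row must sum to 1 within 1e-8")
    if (W < 0).any():
        raise ValueError("weights must be non-negative")
    profiles = subtype_mean_profiles(cohort)
    if W.shape[1] != profiles.shape[1]:
        raise ValueError("weights columns must match the number of programs")
    mu = depth * (profiles.to_numpy() @ W.T)  # genes x n_bulk
    if nb_dispersion is None:
        bulk = mu
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB011]))
        bulk = _nb_sample(rng, mu, nb_dispersion).astype(float)
    names = [f"bulk{i:03d}" for i in range(W.shape[0])]
    bulk_df = pd.DataFrame(bulk, index=profiles.index, columns=names)
    frac_df = pd.DataFrame(W, index=names, columns=profiles.columns)
    return bulk_df, frac_df


# ---------------------------------------------------------------------------
# on-disk representation (MTX + TSV + CSV + JSON)
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write matrix.mtx (genes x cells), genes.tsv, cells.tsv, clinical.csv,
    truth.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = cohort.counts.X
    X = X if sp.issparse(X) else sp.csr_matrix(X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    cohort.annotation[["gene_id", "chromosome", "position"]].to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    obs = cohort.counts.obs.reset_index().rename(columns={"index": "cell_id"})
    obs.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
    t = cohort.truth
    truth_json = dict(
        cutoff=t.cutoff,
        hazard_ratio=t.hazard_ratio,
        coupling=t.coupling,
        lr_pair=list(t.lr_pair),
        sample_basal_fraction=t.sample_basal_fraction.to_dict(),
        patient_basal_fraction=t.patient_basal_fraction.to_dict(),
        segments=t.segment_table.to_dict(orient="records"),
        clone_of_cell=t.clone_of_cell.to_dict(),
        true_program=t.true_program.astype(int).to_dict(),
    )
    (outdir / "truth.json").write_text(json.dumps(truth_json))


def read_cohort_counts(indir: str | Path) -> ad.AnnData:
    """Read matrix.mtx + genes.tsv + cells.tsv back into AnnData (cells x genes)."""
    indir = Path(indir)
    X = scipy.io.mmread(str(indir / "matrix.mtx")).T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t").set_index("gene_id", drop=False)
    genes["order_index"] = genes.groupby("chromosome")["position"].rank().astype(int)
    cells = pd.read_csv(indir / "cells.tsv", sep="\t").set_index("cell_id")
    adata = ad.AnnData(X=X.astype(np.int32), obs=cells, var=genes.drop(columns=["gene_id"]))
    adata.var_names = genes.index
    return adata


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["cnv_segments"] = (
        None if cfg.cnv_segments is None
        else [[c, [s, e], f] for (c, (s, e), f) in cfg.cnv_segments]
    )
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if d.get("cnv_segments"):
        d["cnv_segments"] = [(c, (s, e), f) for c, (s, e), f in d["cnv_segments"]]
    for key in ("segment_span", "gain_folds", "loss_folds", "lm_only_lr_pair"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
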