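"""Bulk/spot deconvolution, composition correlations and ligand-receptor scoring.

Bulk mixtures (or spatial spots) are decomposed into subtype fractions by
non-negative least squares against a signature matrix of per-subtype mean
expression profiles. Subtype proportions are correlated with
immune-compartment proportions and per-sample gene expression. Ligand-
receptor crosstalk between a sender and a receiver cluster is scored per
origin stratum as mean(ligand in sender) x mean(receptor in receiver) with a
within-stratum label-permutation null, in the CellPhoneDB family of scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# NNLS deconvolution
# ---------------------------------------------------------------------------

@dataclass
class MixtureFractions:
    fractions: pd.DataFrame  # samples x K, rows sum to 1 (NaN row when flagged)
    raw_coefficients: pd.DataFrame
    residuals: pd.Series
    flagged: list = field(default_factory=list)  # samples with zero-sum coefficients


def nnls_deconvolve(bulk_matrix: pd.DataFrame, signature_matrix: pd.DataFrame) -> MixtureFractions:
    """Decompose bulk profiles into subtype fractions by NNLS.

    ``bulk_matrix`` is genes x samples and ``signature_matrix`` genes x K;
    genes are matched by id and at least 50 must be shared. Fractions are
    the NNLS coefficients renormalized to the simplex; raw coefficients and
    per-sample residual norms are kept. A zero-sum coefficient vector gives
    a missing (NaN) fraction row with a flag.
    """
    shared = bulk_matrix.index.intersection(signature_matrix.index)
    if len(shared) < 50:
        raise ValueError(f"only {len(shared)} shared genes; need at least 50")
    B = bulk_matrix.loc[shared].to_numpy(dtype=float)
    S = signature_matrix.loc[shared].to_numpy(dtype=float)
    if (B < 0).any() or (S < 0).any():
        raise ValueError("bulk and signature matrices must be non-negative")
    coefs = np.zeros((B.shape[1], S.shape[1]))
    residuals = np.zeros(B.shape[1])
    for j in range(B.shape[1]):
        coefs[j], residuals[j] = nnls(S, B[:, j])
    sums = coefs.sum(axis=1)
    fractions = np.full_like(coefs, np.nan)
    flagged = []
    for j, s in enumerate(sums):
        if s > 0:
            fractions[j] = coefs[j] / s
        else:
            flagged.append(bulk_matrix.columns[j])
            logger.warning("bulk sample %s has all-zero NNLS coefficients", bulk_matrix.columns[j])
    cols = signature_matrix.columns
    return MixtureFractions(
        fractions=pd.DataFrame(fractions, index=bulk_matrix.columns, columns=cols),
        raw_coefficients=pd.DataFrame(coefs, index=bulk_matrix.columns, columns=cols),
        residuals=pd.Series(residuals, index=bulk_matrix.columns, name="residual"),
        flagged=flagged,
    )


def spot_decompose(
    spot_matrix: pd.DataFrame,
    signature_matrix: pd.DataFrame,
    class_a: str | None = None,
    class_b: str | None = None,
):
    """NNLS decomposition of spatial spots plus co-localization.

    A simplified NNLS stand-in for likelihood-based spot decomposition.
    With ``class_a``/``class_b`` named, also returns the Pearson correlation
    (r, p) of the two class fractions across spots. Returns
    ``(MixtureFractions, (r, p) | None)``."""
    mix = nnls_deconvolve(spot_matrix, signature_matrix)
    coloc = None
    if class_a is not None and class_b is not None:
        fa = mix.fractions[class_a]
        fb = mix.fractions[class_b]
        ok = fa.notna() & fb.notna()
        if fa[ok].nunique() <= 1 or fb[ok].nunique() <= 1:
            logger.warning("zero variance in spot fractions; co-localization undefined")
            coloc = (np.nan, np.nan)
        else:
            r, p = pearsonr(fa[ok], fb[ok])
            coloc = (float(r), float(p))
    return mix, coloc


# ---------------------------------------------------------------------------
# composition correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    n_dropped: int = 0
    undefined: bool = False


def proportion_correlation(x_fractions, y_fractions) -> CorrelationResult:
    """Pearson correlation between two per-sample fraction vectors.

    Missing pairs are dropped (and counted); needs >= 3 complete pairs;
    zero variance in either vector gives an undefined, flagged result."""
    x = pd.Series(x_fractions).astype(float)
    y = pd.Series(y_fractions).astype(float)
    y = y.reindex(x.index)
    ok = x.notna() & y.notna()
    n_dropped = int((~ok).sum())
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired samples")
    if x.nunique() <= 1 or y.nunique() <= 1:
        logger.warning("zero variance; proportion correlation undefined")
        return CorrelationResult(r=np.nan, p=np.nan, n=len(x), n_dropped=n_dropped,
                                 undefined=True)
    r, p = pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x), n_dropped=n_dropped)


def gene_vs_fraction_correlation(
    expression,
    gene: str,
    sample_ids,
    class_mask,
    y_fractions,
) -> CorrelationResult:
    """Correlate a gene's per-sample mean normalized expression within a cell
    class against per-sample fractions.

    ``expression`` is a cells x genes DataFrame of library-normalized
    expression; the per-sample summary is the mean over cells of the class.
    """
    if gene not in expression.columns:
        raise KeyError(f"gene {gene!r} absent from the expression matrix")
    sample_ids = pd.Series(np.asarray(sample_ids), index=expression.index)
    class_mask = pd.Series(np.asarray(class_mask, dtype=bool), index=expression.index)
    vals = expression.loc[class_mask, gene]
    per_sample = vals.groupby(sample_ids[class_mask]).mean()
    return proportion_correlation(per_sample, pd.Series(y_fractions))


# ---------------------------------------------------------------------------
# ligand-receptor interaction scoring
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    ligand: str
    receptor: str
    sender: str
    receiver: str
    origin: str
    score: float
    p: float
    n_permutations: int
    present: bool


def interaction_score(
    expression: pd.DataFrame,
    cluster_labels,
    origin_labels,
    lr_pairs,
    sender: str,
    receiver: str,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[InteractionResult]:
    """Permutation-scored ligand-receptor interactions per origin stratum.

    Score = mean normalized ligand expression in the sender cluster x mean
    receptor expression in the receiver cluster within the stratum. The null
    reassigns cluster labels at random within the stratum;
    p = (1 + #{null >= observed}) / (1 + n_permutations), so p is never 0 and
    has resolution 1/(n_permutations + 1). An interaction is "present" iff
    p < alpha and both means are positive. Pairs with missing genes are
    skipped with a log entry.
    """
    clusters = pd.Series(np.asarray(cluster_labels), index=expression.index)
    origins = pd.Series(np.asarray(origin_labels), index=expression.index)
    results: list[InteractionResult] = []
    for origin in pd.unique(origins):
        stratum = origins == origin
        cl = clusters[stratum].to_numpy()
        send_mask = cl == sender
        recv_mask = cl == receiver
        if not send_mask.any() or not recv_mask.any():
            logger.info("stratum %s lacks sender or receiver cells; skipped", origin)
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, abs(hash(str(origin))) % (2**31)])
        )
        for ligand, receptor in lr_pairs:
            if ligand not in expression.columns or receptor not in expression.columns:
                logger.warning("pair (%s, %s) skipped: gene missing", ligand, receptor)
                continue
            lig = expression.loc[stratum, ligand].to_numpy(dtype=float)
            rec = expression.loc[stratum, receptor].to_numpy(dtype=float)
            mean_l = lig[send_mask].mean()
            mean_r = rec[recv_mask].mean()
            observed = mean_l * mean_r
            if observed == 0:
                results.append(InteractionResult(
                    ligand=ligand, receptor=receptor, sender=sender, receiver=receiver,
                    origin=str(origin), score=0.0, p=1.0,
                    n_permutations=n_permutations, present=False,
                ))
                continue
            null = np.empty(n_permutations)
            n = len(cl)
            for b in range(n_permutations):
                perm = rng.permutation(n)
                null[b] = lig[perm[send_mask.nonzero()[0]]].mean() * \
                    rec[perm[recv_mask.nonzero()[0]]].mean()
            p = (1 + int(np.sum(null >= observed))) / (1 + n_permutations)
            present = (p < alpha) and (mean_l > 0) and (mean_r > 0)
            results.append(InteractionResult(
                ligand=ligand, receptor=receptor, sender=sender, receiver=receiver,
                origin=str(origin), score=float(observed), p=float(p),
                n_permutations=n_permutations, present=present,
            ))
    return results


def interactions_to_frame(results: list[InteractionResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
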