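"""Probe-panel validation by gene recall, and cross-dataset signature recall.

Probe recall asks: does a probe's baseline measurement across cell lines
track its own gene's reference expression better than it tracks other
genes?  For each panel gene we Spearman-correlate its measured vector with
every row of a reference expression matrix over the shared cell lines; the
recall rank is the percentage of reference genes with a strictly higher
correlation than the matched gene (0 = perfect).  Ranks are binned
good (<= 5), moderate (> 5 and <= 10) and poor (> 10), and poor probes are
stratified by mean reference expression — low-expressed genes recall badly
for reasons unrelated to probe quality.

Signature recall asks the converse at the signature level: given matched
perturbagens profiled in two datasets, does a query signature retrieve its
own compound's reference signature near the top when ranked by Spearman
correlation?  Signatures first pass a TAS activity filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix

logger = logging.getLogger("cmapneuro")

GOOD_MAX = 5.0
MODERATE_MAX = 10.0


def _bin(rank: float) -> str:
    if rank <= GOOD_MAX:
        return "good"
    if rank <= MODERATE_MAX:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class ProbeRecallResult:
    gene: str
    rho: float
    recall_rank: float  # percentage in [0, 100]
    bin: str
    mean_ref_expression: float


def _rank_standardize(block: np.ndarray) -> np.ndarray:
    """Row-wise rank transform then z-standardize, for fast Spearman via dot."""
    ranks = stats.rankdata(block, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    sd = ranks.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = ranks / sd
    out[~np.isfinite(out)] = 0.0  # constant rows: correlation treated as 0/undefined
    return out


def probe_recall(
    measured: ExpressionMatrix,
    reference: ExpressionMatrix,
) -> list[ProbeRecallResult]:
    """Gene-recall analysis of a measured panel against a reference matrix.

    Columns are aligned by cell-line id (>= 3 shared lines required).  For
    each panel gene the Spearman correlation with every reference row is
    computed; recall_rank = 100 * (# reference genes with strictly higher
    rho) / (total reference genes).  Ties do not count against the matched
    gene.  Panel genes absent from the reference are excluded with a log
    message; constant measured vectors are flagged with rho = NaN.
    """
    shared = [c for c in measured.sample_ids if c in set(reference.sample_ids)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared cell lines, found {len(shared)}")
    M = measured.values[shared]
    R = reference.values[shared]
    n_ref = len(R)
    ref_index = {g: i for i, g in enumerate(R.index)}

    Rstd = _rank_standardize(R.to_numpy(dtype=float))
    Mstd = _rank_standardize(M.to_numpy(dtype=float))
    C = len(shared)
    rho_matrix = (Mstd @ Rstd.T) / C  # panel genes × reference genes
    ref_means = reference.values.mean(axis=1)

    results = []
    for i, gene in enumerate(M.index):
        j = ref_index.get(gene)
        if j is None:
            logger.warning("panel gene %s absent from reference; excluded", gene)
            continue
        if np.all(Mstd[i] == 0) or np.all(Rstd[j] == 0):
            logger.warning("constant vector for gene %s: correlation undefined", gene)
            results.append(ProbeRecallResult(gene, float("nan"), float("nan"),
                                             "unmatched", float(ref_means.loc[gene])))
            continue
        rho_g = rho_matrix[i, j]
        higher = int((np.delete(rho_matrix[i], j) > rho_g).sum())
        # count the matched gene itself in the denominator, per the
        # "percentage of the N reference genes" convention
        rank = 100.0 * higher / n_ref
        results.append(
            ProbeRecallResult(gene, float(rho_g), float(rank), _bin(rank),
                              float(ref_means.loc[gene]))
        )
    return results


def recall_summary(results: list[ProbeRecallResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    return df


def stratify_recall_by_expression(
    results: list[ProbeRecallResult],
    low_expression_threshold: float | None = None,
) -> pd.DataFrame:
    """Counts and fractions of low-expression genes per recall bin.

    The low-expression cutoff defaults to the lower tertile of mean
    reference expression over the analyzed genes.
    """
    if not results:
        raise ValueError("no recall results to stratify")
    df = pd.DataFrame([r.__dict__ for r in results])
    df = df[df["bin"].isin(["good", "moderate", "poor"])]
    if low_expression_threshold is None:
        low_expression_threshold = float(np.quantile(df["mean_ref_expression"], 1 / 3))
    df = df.assign(low=df["mean_ref_expression"] < low_expression_threshold)
    rows = []
    for b in ["good", "moderate", "poor"]:
        sub = df[df["bin"] == b]
        n, n_low = len(sub), int(sub["low"].sum())
        rows.append(
            {"bin": b, "n": n, "n_low_expression": n_low,
             "fraction_low": n_low / n if n else 0.0}
        )
    return pd.DataFrame(rows).set_index("bin")


@dataclass(frozen=True)
class SignatureRecallResult:
    pert_id: str
    query_signature_id: str
    rank: int  # 1 = best
    rho_matched: float
    active: bool
    recalled: bool


def signature_recall(
    query_sigs: ExpressionMatrix,
    query_metrics: pd.DataFrame,
    reference_sigs: ExpressionMatrix,
    gene_space: list[str] | None = None,
    tas_threshold: float = 0.212,
    rank_threshold: int = 190,
) -> tuple[list[SignatureRecallResult], float]:
    """Rank each active query signature's own perturbagen in a reference corpus.

    Both datasets are restricted to the shared ``gene_space``; matching is
    by perturbagen id.  Only query signatures with TAS >= ``tas_threshold``
    enter the recall denominator.  The rank of the matched perturbagen is
    the best (competition) rank among its reference signatures: 1 + the
    number of reference signatures with strictly higher Spearman
    correlation.  Returns the per-signature results plus the recall
    fraction over active signatures.
    """
    if gene_space is None:
        gene_space = [g for g in query_sigs.gene_ids if g in set(reference_sigs.gene_ids)]
    Q = query_sigs.values.loc[gene_space]
    R = reference_sigs.values.loc[gene_space]
    q_meta = query_sigs.meta_frame()
    r_meta = reference_sigs.meta_frame()
    ref_perts = r_meta["perturbagen_id"].to_numpy()

    Qstd = _rank_standardize(Q.to_numpy(dtype=float).T).T
    Rstd = _rank_standardize(R.to_numpy(dtype=float).T).T
    rho = (Qstd.T @ Rstd) / len(gene_space)  # query sigs × reference sigs

    results = []
    n_active = n_recalled = 0
    for qi, sig_id in enumerate(Q.columns):
        pert = q_meta.loc[sig_id, "perturbagen_id"]
        t = float(query_metrics.loc[sig_id, "tas"])
        active = t >= tas_threshold
        matched = np.where(ref_perts == pert)[0]
        if len(matched) == 0:
            logger.warning("perturbagen %s absent from reference; excluded", pert)
            continue
        best = matched[np.argmax(rho[qi, matched])]
        rank = 1 + int((rho[qi] > rho[qi, best]).sum())
        recalled = active and rank <= rank_threshold
        if active:
            n_active += 1
            n_recalled += int(recalled)
        results.append(
            SignatureRecallResult(pert, sig_id, rank, float(rho[qi, best]),
                                  active, recalled)
        )
    if n_active == 0:
        logger.warning("no query signatures pass the TAS activity filter")
        return results, float("nan")
    return results, n_recalled / n_active
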