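"""Connectivity queries: weighted enrichment → WTCS → NCS → tau.

A query is a pair of disjoint up/down gene sets.  Against each Level 5
signature (genes ranked by z-score, descending) we compute a weighted
Kolmogorov–Smirnov enrichment score for each set: member genes step the
running sum up in proportion to |z| (normalized over members), non-members
step it down by 1/(N - |S|); ES is the running-sum extremum of largest
magnitude.  The weighted connectivity score combines the two:

    WTCS = (ES_up - ES_down) / 2   if ES_up and ES_down have opposite signs
         = 0                       otherwise.

WTCS values are normalized within each cell_line × perturbagen-type
stratum (NCS = WTCS divided by the mean |WTCS| of same-sign scores in the
stratum) and converted to a signed percentile tau in [-100, 100] against a
reference distribution of |NCS| for the stratum.  Per-perturbagen
connectivity is summarized as the median tau across that perturbagen's
signatures (cell lines, doses, times): positive median tau = the
perturbagen mimics the queried expression change, negative = it reverses
it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import DEGTable, ExpressionMatrix, QueryGeneSets

logger = logging.getLogger("cmapneuro")


# ---------------------------------------------------------------------------
# Query-set construction from DEG tables
# ---------------------------------------------------------------------------

def build_query_sets(
    degs: DEGTable,
    n_up: int = 150,
    n_down: int = 150,
    sort_key: str = "abs_log2fc",
) -> QueryGeneSets:
    """Split a DEG table into top up- and down-regulated query sets.

    ``sort_key='abs_log2fc'`` ranks genes by |log2FC| within each sign;
    ``'signed_log2fc'`` ranks positives descending and negatives ascending
    (most extreme first in both cases — the two keys differ only when
    combined with pre-filtering, but both are exposed).  If fewer genes of
    a sign exist than requested, the set is truncated with a log message.
    """
    if n_up < 1 or n_down < 1:
        raise ValueError("n_up and n_down must be >= 1")
    df = degs.records
    pos = df[df["log2fc"] > 0]
    neg = df[df["log2fc"] < 0]
    if pos.empty or neg.empty:
        raise ValueError("query needs both positive and negative log2FC genes")
    if sort_key == "abs_log2fc":
        pos = pos.reindex(pos["log2fc"].abs().sort_values(ascending=False).index)
        neg = neg.reindex(neg["log2fc"].abs().sort_values(ascending=False).index)
    elif sort_key == "signed_log2fc":
        pos = pos.sort_values("log2fc", ascending=False)
        neg = neg.sort_values("log2fc", ascending=True)
    else:
        raise ValueError(f"unknown sort_key: {sort_key}")
    if len(pos) < n_up:
        logger.info("only %d positive-log2FC genes for requested %d", len(pos), n_up)
    if len(neg) < n_down:
        logger.info("only %d negative-log2FC genes for requested %d", len(neg), n_down)
    return QueryGeneSets(
        up=frozenset(pos["gene_symbol"].head(n_up)),
        down=frozenset(neg["gene_symbol"].head(n_down)),
    )


# ---------------------------------------------------------------------------
# Weighted KS enrichment and WTCS
# ---------------------------------------------------------------------------

class NoOverlapError(ValueError):
    """The query set shares no genes with the signature's gene space."""


def weighted_es(z: pd.Series, gene_set: frozenset[str] | set[str]) -> float:
    """Weighted KS enrichment of ``gene_set`` in the z-ranked signature.

    Genes are ranked by z descending; member positions step the running
    sum up by |z| / sum(|z| over members), others step down 1/(N - |S|).
    ES is the running-sum value of maximal magnitude; positive ES means
    the set concentrates at the top of the ranking.
    """
    order = np.argsort(-z.to_numpy(), kind="mergesort")
    genes = z.index.to_numpy()[order]
    zvals = np.abs(z.to_numpy()[order])
    member = np.isin(genes, list(gene_set))
    n_hit = int(member.sum())
    if n_hit == 0:
        raise NoOverlapError("gene set has no overlap with the signature")
    N = len(genes)
    if n_hit == N:
        # degenerate: no misses to step down; the running sum ends at +1
        return 1.0
    w = np.zeros(N)
    denom = zvals[member].sum()
    if denom == 0:
        w[member] = 1.0 / n_hit  # all-zero weights fall back to unweighted KS
    else:
        w[member] = zvals[member] / denom
    w[~member] = -1.0 / (N - n_hit)
    running = np.cumsum(w)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def wtcs(z: pd.Series, q: QueryGeneSets) -> tuple[float, float, float]:
    """Weighted connectivity score of a query against one signature.

    Returns (es_up, es_down, wtcs); wtcs = (es_up - es_down)/2 when the two
    enrichment scores have opposite signs, else 0.
    """
    es_up = weighted_es(z, q.up)
    es_down = weighted_es(z, q.down)
    if es_up * es_down < 0:
        w = (es_up - es_down) / 2.0
    else:
        w = 0.0
    return es_up, es_down, w


# ---------------------------------------------------------------------------
# Normalization and tau
# ---------------------------------------------------------------------------

@dataclass
class TouchstoneReference:
    """A signature corpus with metadata and optional tau reference
    distributions per (cell_line, pert_type) stratum."""

    signatures: ExpressionMatrix
    pert_types: dict[str, str] = field(default_factory=dict)  # sig id -> CP/CTRL/KD/OE
    ncs_reference: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for sid in self.signatures.sample_ids:
            self.pert_types.setdefault(sid, "CP")

    def stratum_of(self, sig_id: str) -> tuple[str, str]:
        meta = {s.sample_id: s for s in self.signatures.samples}
        return meta[sig_id].cell_line, self.pert_types[sig_id]


def ncs_tau(raw: pd.DataFrame, reference: TouchstoneReference) -> pd.DataFrame:
    """Attach NCS and tau columns to a raw WTCS result table.

    NCS = wtcs / mean(|wtcs| of same-sign scores in the signature's
    cell_line × pert_type stratum).  Tau = sign(ncs) * 100 * fraction of the
    stratum's reference |NCS| strictly below |NCS| (ties excluded); when no
    precomputed reference distribution exists for a stratum, the NCS values
    of the current batch in that stratum serve as the reference.
    """
    df = raw.copy()
    df["stratum"] = [reference.stratum_of(s) for s in df["signature_id"]]
    ncs = np.zeros(len(df))
    for stratum, idx in df.groupby("stratum", sort=False).groups.items():
        w = df.loc[idx, "wtcs"].to_numpy(dtype=float)
        if len(w) == 0:
            raise ValueError(f"empty stratum {stratum}")
        pos_mean = np.abs(w[w > 0]).mean() if (w > 0).any() else np.nan
        neg_mean = np.abs(w[w < 0]).mean() if (w < 0).any() else np.nan
        out = np.zeros_like(w)
        out[w > 0] = w[w > 0] / pos_mean
        out[w < 0] = w[w < 0] / neg_mean
        ncs[df.index.get_indexer(idx)] = out
    df["ncs"] = ncs

    tau = np.zeros(len(df))
    for stratum, idx in df.groupby("stratum", sort=False).groups.items():
        batch = df.loc[idx, "ncs"].to_numpy(dtype=float)
        ref = reference.ncs_reference.get(stratum)
        ref_abs = np.abs(batch if ref is None else np.asarray(ref, dtype=float))
        if len(ref_abs) == 0:
            raise ValueError(f"empty tau reference for stratum {stratum}")
        a = np.abs(batch)
        frac = (ref_abs[None, :] < a[:, None]).mean(axis=1)
        tau[df.index.get_indexer(idx)] = np.sign(batch) * 100.0 * frac
    df["tau"] = tau
    return df.drop(columns="stratum")


# ---------------------------------------------------------------------------
# Full query
# ---------------------------------------------------------------------------

def query(
    q: QueryGeneSets,
    corpus: TouchstoneReference,
    aggregate: str = "median",
    top_k: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a query against every corpus signature and rank perturbagens.

    Query symbols absent from the signature gene space are dropped (with a
    logged count) — the unavoidable cost of querying a targeted panel with
    transcriptome-wide DEG lists.  Returns (per-signature table, per-
    perturbagen table sorted by descending median tau, with mimic/reverse
    labels on the top/bottom ``top_k``).
    """
    if aggregate != "median":
        raise ValueError("only median aggregation is supported")
    sigs = corpus.signatures
    space = set(sigs.gene_ids)
    up = frozenset(g for g in q.up if g in space)
    down = frozenset(g for g in q.down if g in space)
    dropped = (len(q.up) - len(up)) + (len(q.down) - len(down))
    if dropped:
        logger.info("%d query genes not on the panel were dropped", dropped)
    if not up or not down:
        raise NoOverlapError("query sets share no genes with the corpus panel")
    qq = QueryGeneSets(up=up, down=down)

    meta = sigs.meta_frame()
    rows = []
    for sid in sigs.sample_ids:
        try:
            es_up, es_down, w = wtcs(sigs.values[sid], qq)
        except NoOverlapError:
            logger.warning("signature %s excluded: no query overlap", sid)
            continue
        m = meta.loc[sid]
        rows.append(
            {"signature_id": sid, "pert_id": m["perturbagen_id"],
             "cell_line": m["cell_line"], "dose": m["dose"], "time": m["time"],
             "es_up": es_up, "es_down": es_down, "wtcs": w}
        )
    per_sig = ncs_tau(pd.DataFrame(rows), corpus)

    agg = (
        per_sig.groupby("pert_id")["tau"].median().sort_values(ascending=False)
        .rename("median_tau").to_frame().reset_index()
    )
    labels = np.array(["none"] * len(agg), dtype=object)
    head = agg.head(top_k)
    labels[head.index[head["median_tau"] > 0]] = "mimic"
    tail = agg.tail(top_k)
    labels[tail.index[tail["median_tau"] < 0]] = "reverse"
    agg["label"] = labels
    return per_sig, agg


def query_sets_from_signature(z: pd.Series, n: int = 50) -> QueryGeneSets:
    """Top/bottom-n genes of a signature as up/down query sets."""
    order = z.sort_values(ascending=False)
    return QueryGeneSets(up=frozenset(order.index[:n]),
                         down=frozenset(order.index[-n:]))


def touchstone_similarity(
    pert_id: str,
    corpus: TouchstoneReference,
    per_stratum: bool = False,
    set_size: int = 50,
) -> pd.DataFrame:
    """Perturbagen–perturbagen similarity via self-derived query sets.

    Each signature of the selected perturbagen queries the rest of the
    corpus with its own top/bottom ``set_size`` genes.  Results are
    reported per query signature; with ``per_stratum`` the perturbagen
    ranking is aggregated within each cell line separately.
    """
    sigs = corpus.signatures
    meta = sigs.meta_frame()
    own = meta.index[meta["perturbagen_id"] == pert_id]
    if len(own) == 0:
        def _canon(s: str) -> str:
            return "".join(ch for ch in s.lower() if ch.isalnum())

        known = sorted(set(meta["perturbagen_id"]))
        cq = _canon(pert_id)
        near = [p for p in known if cq[:4] and (cq[:4] in _canon(p) or _canon(p)[:4] in cq)]
        raise KeyError(f"perturbagen {pert_id!r} not in corpus; near matches: {near[:5]}")
    frames = []
    for sid in own:
        q = query_sets_from_signature(sigs.values[sid], n=set_size)
        per_sig, _ = query(q, corpus)
        per_sig = per_sig[per_sig["signature_id"] != sid].copy()
        per_sig["query_signature_id"] = sid
        per_sig["query_cell_line"] = meta.loc[sid, "cell_line"]
        frames.append(per_sig)
    out = pd.concat(frames, ignore_index=True)
    group_cols = ["query_cell_line", "pert_id"] if per_stratum else ["pert_id"]
    ranking = (
        out.groupby(group_cols)["tau"].median().rename("median_tau").reset_index()
        .sort_values(group_cols[:-1] + ["median_tau"], ascending=[True] * (len(group_cols) - 1) + [False])
        .reset_index(drop=True)
    )
    return ranking
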