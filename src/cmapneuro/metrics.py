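"""Signature quality metrics: CC, SS and TAS.

CC (replicate correlation) is the 75th quantile of the pairwise Spearman
correlations among a condition's Level 4 replicates.  SS (signature
strength) counts panel genes whose replicate-adjusted absolute z-score
exceeds 2, with Za = Z * sqrt(N).  TAS combines the two, normalized by the
panel size G:

    TAS = sqrt( SS * max(CC, 0) / G )

so TAS lies in [0, 1], is zero for irreproducible signatures (CC <= 0) and
reaches 1 only when every panel gene is strongly and reproducibly moved.
The unadjusted-SS and non-sqrt TAS variants are kept behind configuration
switches for sensitivity checks.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, Level

logger = logging.getLogger("cmapneuro")

#: Sentinel for CC when a signature has a single replicate.
CC_UNDEFINED = float("nan")


@dataclass(frozen=True)
class SignatureMetrics:
    signature_id: str
    n: int
    cc: float  # NaN when undefined (n = 1)
    ss: int
    tas: float
    G: int


def replicate_correlation(replicates: np.ndarray) -> float:
    """75th quantile (linear interpolation) of pairwise Spearman correlations.

    ``replicates`` is genes × n.  n = 1 returns NaN (undefined; TAS treats
    it as 0).  Pairs involving a constant vector have undefined correlation
    and are excluded with a warning; if every pair is excluded the result
    is NaN.
    """
    replicates = np.asarray(replicates, dtype=float)
    n = replicates.shape[1]
    if n < 2:
        logger.info("replicate correlation undefined for a single replicate")
        return CC_UNDEFINED
    rhos = []
    for i, j in itertools.combinations(range(n), 2):
        rho = stats.spearmanr(replicates[:, i], replicates[:, j]).statistic
        if np.isnan(rho):
            logger.warning("constant replicate vector: pair (%d,%d) excluded", i, j)
            continue
        rhos.append(rho)
    if not rhos:
        return CC_UNDEFINED
    return float(np.percentile(rhos, 75, method="linear"))


def signature_strength(z: np.ndarray, n: int, ss_variant: str = "sqrt_n") -> int:
    """Count of genes with replicate-adjusted |z| above 2.

    Default adjustment Za = Z * sqrt(n); ``ss_variant='unadjusted'`` uses
    Za = Z.  The inequality is strict (|Za| > 2).
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("signature contains non-finite z-scores")
    if n < 1:
        raise ValueError("replicate count must be >= 1")
    if ss_variant == "sqrt_n":
        za = z * math.sqrt(n)
    elif ss_variant == "unadjusted":
        za = z
    else:
        raise ValueError(f"unknown ss_variant: {ss_variant}")
    return int((np.abs(za) > 2.0).sum())


def tas(ss: float, cc: float, G: int, tas_variant: str = "sqrt") -> float:
    """Transcriptional activity score from SS, CC and panel size G.

    NaN CC (undefined, single replicate) is treated as 0, so TAS = 0.
    """
    if G <= 0:
        raise ValueError("panel size G must be positive")
    if ss > G:
        raise ValueError(f"SS = {ss} exceeds panel size G = {G}")
    cc_eff = 0.0 if (cc is None or np.isnan(cc)) else max(float(cc), 0.0)
    q = float(ss) * cc_eff / G
    if tas_variant == "sqrt":
        return math.sqrt(q)
    if tas_variant == "literal":
        return q
    raise ValueError(f"unknown tas_variant: {tas_variant}")


def annotate_signatures(
    m5: ExpressionMatrix,
    m4: ExpressionMatrix,
    groups: dict[str, list[str]] | None = None,
    G: int | None = None,
    ss_variant: str = "sqrt_n",
    tas_variant: str = "sqrt",
) -> pd.DataFrame:
    """Per-signature metrics table (n, cc, ss, tas) joined to sample metadata.

    ``groups`` maps each Level 5 signature id to its Level 4 replicate
    columns; it defaults to the replicate_group provenance on m4.
    """
    if m5.level != Level.L5_SIGNATURE or m4.level != Level.L4_ZSCORE:
        raise ValueError("annotate_signatures needs a Level 5 and a Level 4 matrix")
    if groups is None:
        groups = {}
        for s in m4.samples:
            groups.setdefault(s.replicate_group or s.sample_id, []).append(s.sample_id)
    missing = set(m5.sample_ids) - set(groups)
    if missing:
        raise ValueError(f"signatures with no replicate group mapping: {sorted(missing)[:5]}")
    G = G or m5.values.shape[0]
    meta = m5.meta_frame()
    rows = []
    for sig_id in m5.sample_ids:
        members = groups[sig_id]
        n = len(members)
        cc = replicate_correlation(m4.values[members].to_numpy()) if n >= 2 else CC_UNDEFINED
        ss = signature_strength(m5.values[sig_id].to_numpy(), n, ss_variant)
        t = tas(ss, cc, G, tas_variant)
        if n == 1:
            logger.info("signature %s: single replicate, cc undefined, tas = 0", sig_id)
        m = meta.loc[sig_id]
        rows.append(
            {
                "signature_id": sig_id, "cell_line": m["cell_line"],
                "pert_id": m["perturbagen_id"], "dose": m["dose"], "time": m["time"],
                "n": n, "cc": cc, "ss": ss, "tas": t,
            }
        )
    return pd.DataFrame(rows).set_index("signature_id")
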