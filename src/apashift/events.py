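"""Direction, basal-state, temporal and costimulation classification of
APA events, plus cross-condition correlation.

Works on the event tables produced by :mod:`apashift.quant`: one row per
gene per pairwise comparison with ``dpdui``, ``p_raw``, ``p_adj`` and a
categorical ``call``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import ValidationError
from .quant import (CALL_LENGTHENED, CALL_NON_CHANGING, CALL_SHORTENED)

SIGNIFICANT_CALLS = (CALL_SHORTENED, CALL_LENGTHENED)

TEMPORAL_8H_ONLY = "8h_only"
TEMPORAL_48H_ONLY = "48h_only"
TEMPORAL_BOTH = "both"
TEMPORAL_OTHER = "other"


def direction_summary(events: pd.DataFrame) -> dict[str, int]:
    """Counts of significantly shortened vs lengthened events."""
    calls = events["call"]
    return {
        "shortened": int((calls == CALL_SHORTENED).sum()),
        "lengthened": int((calls == CALL_LENGTHENED).sum()),
    }


def basal_pdui_bin(basal_pdui: float,
                   long_cut: float = 66.0,
                   short_cut: float = 33.0) -> str:
    """Tertile bin of the unstimulated PDUI.

    ``long`` strictly above ``long_cut`` (genes predominantly expressing
    the long 3'UTR at baseline), ``short`` strictly below ``short_cut``,
    ``mid`` otherwise; both boundaries are exclusive.
    """
    if not (0.0 <= basal_pdui <= 100.0):
        raise ValidationError(f"basal PDUI {basal_pdui} outside [0, 100]")
    if basal_pdui > long_cut:
        return "long"
    if basal_pdui < short_cut:
        return "short"
    return "mid"


def temporal_classify(call_early: pd.Series | np.ndarray,
                      call_late: pd.Series | np.ndarray) -> np.ndarray:
    """Partition genes by when their APA change is significant.

    ``48h_only``: significant at the late time point and strictly
    non-changing at the early one (the strict definition: an
    indeterminate early call is excluded); ``8h_only`` symmetric;
    ``both``: significant at both; ``other``: everything else.  Every
    gene receives exactly one label.
    """
    early = np.asarray(call_early, dtype=object)
    late = np.asarray(call_late, dtype=object)
    sig_e = np.isin(early, SIGNIFICANT_CALLS)
    sig_l = np.isin(late, SIGNIFICANT_CALLS)
    out = np.full(early.shape, TEMPORAL_OTHER, dtype=object)
    out[sig_e & sig_l] = TEMPORAL_BOTH
    out[sig_l & (early == CALL_NON_CHANGING)] = TEMPORAL_48H_ONLY
    out[sig_e & (late == CALL_NON_CHANGING)] = TEMPORAL_8H_ONLY
    return out


@dataclass(frozen=True)
class CD28Ratio:
    ratio: float
    enhanced: bool
    discordant: bool


def cd28_ratio(dpdui_cd3cd28: float, dpdui_cd3: float,
               floor: float = 1.0, threshold: float = 2.0) -> CD28Ratio:
    """Fold change of APA magnitude under costimulation vs CD3 alone.

    ratio = |dPDUI_CD3/CD28| / max(|dPDUI_CD3|, floor); the floor (1
    percentage point by default) prevents near-zero CD3 effects from
    skewing the ratio.  ``enhanced`` flags a more-than-``threshold``-fold
    increase.  Sign-discordant pairs (shortening under one stimulus,
    lengthening under the other, both beyond the floor) are flagged
    rather than silently folded into the ratio.
    """
    num = abs(dpdui_cd3cd28)
    den = max(abs(dpdui_cd3), floor)
    ratio = num / den
    discordant = (dpdui_cd3cd28 * dpdui_cd3 < 0
                  and abs(dpdui_cd3) >= floor
                  and abs(dpdui_cd3cd28) >= floor)
    return CD28Ratio(ratio=ratio, enhanced=ratio > threshold,
                     discordant=discordant)


def cd28_ratio_table(events_cd3cd28: pd.DataFrame, events_cd3: pd.DataFrame,
                     floor: float = 1.0, threshold: float = 2.0) -> pd.DataFrame:
    """Per-gene costimulation ratios over events significant under CD3/CD28."""
    cc = events_cd3cd28.set_index("gene_id")
    c3 = events_cd3.set_index("gene_id")
    sig = cc.index[cc["call"].isin(SIGNIFICANT_CALLS)]
    rows = []
    for gene in sig:
        if gene not in c3.index:
            continue
        r = cd28_ratio(float(cc.loc[gene, "dpdui"]), float(c3.loc[gene, "dpdui"]),
                       floor=floor, threshold=threshold)
        rows.append({"gene_id": gene, "dpdui_cd3cd28": cc.loc[gene, "dpdui"],
                     "dpdui_cd3": c3.loc[gene, "dpdui"], "ratio": r.ratio,
                     "enhanced": r.enhanced, "discordant": r.discordant})
    return pd.DataFrame(rows, columns=["gene_id", "dpdui_cd3cd28", "dpdui_cd3",
                                       "ratio", "enhanced", "discordant"])


def condition_correlation(x: np.ndarray, y: np.ndarray
                          ) -> tuple[float, float, float]:
    """Pearson r plus OLS slope/intercept of paired dPDUI vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired vectors of equal length required")
    if x.size < 3:
        raise ValidationError("need at least 3 paired events")
    r = float(stats.pearsonr(x, y)[0])
    res = stats.linregress(x, y)
    return r, float(res.slope), float(res.intercept)


def comparison_table(events_by_comparison: dict[str, pd.DataFrame],
                     basal: pd.Series | None = None) -> pd.DataFrame:
    """Wide per-gene table: dpdui and call per comparison, plus basal PDUI."""
    pieces = []
    for name, ev in events_by_comparison.items():
        sub = ev.set_index("gene_id")[["dpdui", "call"]]
        sub.columns = [f"dpdui_{name}", f"call_{name}"]
        pieces.append(sub)
    table = pd.concat(pieces, axis=1, join="outer")
    if basal is not None:
        table["basal_pdui"] = basal
    table.index.name = "gene_id"
    return table


def correlation_pairs(events_a: pd.DataFrame, events_b: pd.DataFrame,
                      mode: str = "union") -> tuple[np.ndarray, np.ndarray]:
    """Paired dPDUI vectors restricted to significant events.

    ``mode="union"``: events significant in either comparison;
    ``"intersection"``: significant in both.
    """
    a = events_a.set_index("gene_id")
    b = events_b.set_index("gene_id")
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    sig_a = a["call"].isin(SIGNIFICANT_CALLS)
    sig_b = b["call"].isin(SIGNIFICANT_CALLS)
    mask = (sig_a | sig_b) if mode == "union" else (sig_a & sig_b)
    return a.loc[mask, "dpdui"].to_numpy(), b.loc[mask, "dpdui"].to_numpy()
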