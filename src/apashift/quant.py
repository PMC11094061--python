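"""De-novo proximal PAS estimation and PDUI quantification.

The two-segment coverage model
------------------------------

Per-base coverage of a two-isoform 3'UTR is modelled as

    depth(x) ~ w_L + w_S * 1[x < b]

where ``w_L`` is the abundance of the long (distal) isoform, ``w_S``
the abundance of the short (proximal) isoform and ``b`` the breakpoint,
i.e. the de-novo proximal cleavage site.  For a fixed ``b`` the
non-negative least-squares solution is closed form: the long abundance
is the mean coverage downstream of ``b`` and the short abundance the
upstream-downstream mean difference, clamped at zero (in which case the
single free parameter refits to the overall mean).  The breakpoint is
chosen to minimize the residual sum of squares jointly across all
samples of a gene — a single shared proximal site per gene — and the
percentage of distal polyA site usage is

    PDUI = 100 * w_L / (w_L + w_S)

per sample (100 = all transcripts reach the distal site, 0 = all stop
at the proximal site).

Event testing
-------------

A pairwise comparison reports dPDUI = mean(PDUI_stim) - mean(PDUI_ref)
and a p-value, by default from Fisher's exact test on the pooled
rounded long/short abundances of each group (well behaved at three
replicates per group); a Welch t-test on per-replicate PDUI is
available as an alternative.  Batch calling applies Benjamini-Hochberg
adjustment and the thresholds: significant shortening/lengthening needs
|dPDUI| >= 20 at adjusted p < 0.05; non-changing needs |dPDUI| < 3 with
raw p > 0.05; everything else is indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageTrack, ValidationError

QC_OK = "ok"
QC_LOW_COVERAGE = "low_coverage"
QC_NO_BREAKPOINT = "no_breakpoint"

CALL_SHORTENED = "shortened"
CALL_LENGTHENED = "lengthened"
CALL_NON_CHANGING = "non_changing"
CALL_INDETERMINATE = "indeterminate"


@dataclass
class PDUIFit:
    """Fitted shared breakpoint plus per-sample abundances and PDUI."""

    gene_id: str
    breakpoint: int | None
    sample_ids: list[str]
    w_long: np.ndarray
    w_short: np.ndarray
    pdui: np.ndarray
    residual_ss: float
    qc_flag: str


def _segment_fit_at(D: np.ndarray, b: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form NNLS of the two-segment model at breakpoint ``b``.

    Returns per-sample (w_long, w_short) and the total residual sum of
    squares, with the non-negativity clamp applied.
    """
    up_mean = D[:, :b].mean(axis=1)
    dn_mean = D[:, b:].mean(axis=1)
    w_long = dn_mean.copy()
    w_short = up_mean - dn_mean
    clamp = w_short < 0
    if np.any(clamp):
        w_short[clamp] = 0.0
        w_long[clamp] = D[clamp].mean(axis=1)
    upper = w_long + w_short
    rss = float(((D[:, :b] - upper[:, None]) ** 2).sum()
                + ((D[:, b:] - w_long[:, None]) ** 2).sum())
    return w_long, w_short, rss


def fit_two_segment(
    tracks: list[CoverageTrack] | np.ndarray,
    gene_id: str = "",
    sample_ids: list[str] | None = None,
    search_min: int = 100,
    min_mean_depth: float = 1.0,
    min_fit_gain: float = 0.05,
    require_normalized: bool = True,
) -> PDUIFit:
    """Fit the shared proximal breakpoint and per-sample PDUI of one gene.

    Parameters
    ----------
    tracks:
        All samples of one gene (any condition), as
        :class:`~apashift.coverage.CoverageTrack` objects or a
        ``(n_samples, L)`` array of normalized depths in transcript
        orientation.
    search_min:
        The breakpoint is searched in ``[search_min, L - search_min]``;
        guards against degenerate edge breakpoints.
    min_mean_depth:
        At least one sample must reach this mean depth, otherwise the
        gene is flagged ``low_coverage`` and not fitted.
    min_fit_gain:
        Minimum relative residual reduction of the best two-segment fit
        over the one-segment (flat) fit; below it the gene is flagged
        ``no_breakpoint`` (values are still reported at the best
        breakpoint).

    Ties in the residual are broken toward the most distal breakpoint,
    which is deterministic and biases against spurious shortening calls.
    """
    if isinstance(tracks, np.ndarray):
        D = np.atleast_2d(np.asarray(tracks, dtype=float))
    else:
        if not tracks:
            raise ValidationError("no tracks supplied")
        lengths = {t.depth.size for t in tracks}
        if len(lengths) != 1:
            raise ValidationError(f"{gene_id or tracks[0].gene_id}: "
                                  "unequal track lengths")
        if require_normalized and not all(t.normalized for t in tracks):
            raise ValidationError("fit_two_segment requires normalized tracks")
        gene_id = gene_id or tracks[0].gene_id
        sample_ids = sample_ids or [t.sample_id for t in tracks]
        D = np.vstack([t.depth for t in tracks])
    n, L = D.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if L < 2 * search_min:
        raise ValidationError(
            f"{gene_id}: UTR length {L} < 2 * search_min ({2 * search_min})")

    if float(D.mean(axis=1).max()) < min_mean_depth:
        nan = np.full(n, np.nan)
        return PDUIFit(gene_id, None, list(sample_ids), nan.copy(), nan.copy(),
                       nan.copy(), float("nan"), QC_LOW_COVERAGE)

    # Residuals for every candidate breakpoint via prefix sums.
    c1 = np.zeros((n, L + 1))
    c1[:, 1:] = np.cumsum(D, axis=1)
    c2 = np.zeros((n, L + 1))
    c2[:, 1:] = np.cumsum(D * D, axis=1)
    tot1 = c1[:, -1:]
    tot2 = c2[:, -1:]

    bs = np.arange(search_min, L - search_min + 1)
    up_n = bs.astype(float)
    dn_n = (L - bs).astype(float)
    up_sum = c1[:, bs]
    dn_sum = tot1 - up_sum
    rss_two = (c2[:, bs] - up_sum**2 / up_n) + (tot2 - c2[:, bs] - dn_sum**2 / dn_n)
    rss_flat = tot2 - tot1**2 / L
    clamped = up_sum / up_n < dn_sum / dn_n
    rss = np.where(clamped, rss_flat, rss_two).sum(axis=0)

    best = int(np.flatnonzero(rss == rss.min()).max())  # distal-most tie-break
    b = int(bs[best])

    w_long, w_short, rss_best = _segment_fit_at(D, b)
    flat_means = D.mean(axis=1, keepdims=True)
    flat_total = float(((D - flat_means) ** 2).sum())

    denom = w_long + w_short
    pdui = np.full(n, np.nan)
    nz = denom > 0
    pdui[nz] = 100.0 * w_long[nz] / denom[nz]

    if flat_total <= 0 or rss_best > (1.0 - min_fit_gain) * flat_total:
        qc = QC_NO_BREAKPOINT
    else:
        qc = QC_OK
    return PDUIFit(gene_id, b, list(sample_ids), w_long, w_short, pdui,
                   rss_best, qc)


def fits_to_frame(fits: list[PDUIFit],
                  sample_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format table: one row per gene x sample.

    ``sample_meta`` (indexed or keyed by sample_id with ``condition``
    and ``replicate`` columns) annotates each row when provided.
    """
    rows = []
    for fit in fits:
        for i, sid in enumerate(fit.sample_ids):
            rows.append({
                "gene_id": fit.gene_id,
                "breakpoint": fit.breakpoint if fit.breakpoint is not None else np.nan,
                "qc_flag": fit.qc_flag,
                "sample_id": sid,
                "w_long": fit.w_long[i],
                "w_short": fit.w_short[i],
                "pdui": fit.pdui[i],
                "residual_ss": fit.residual_ss,
            })
    df = pd.DataFrame(rows)
    if sample_meta is not None and len(df):
        meta = sample_meta.set_index("sample_id")[["condition", "replicate"]]
        df = df.join(meta, on="sample_id")
    return df


def test_event(
    gene_fits: pd.DataFrame,
    ref_condition: str,
    stim_condition: str,
    method: str = "fisher",
) -> tuple[float, float, float, float]:
    """dPDUI and raw p for one gene and one pairwise comparison.

    Returns ``(mean_pdui_ref, mean_pdui_stim, dpdui, p_raw)``.  With
    fewer than two samples in either group the p-value is 1 and the
    dPDUI is still reported.  ``method="fisher"`` tests the 2x2 table of
    pooled rounded long/short abundances; ``method="welch"`` runs an
    unequal-variance t-test on per-replicate PDUI.
    """
    ref = gene_fits[gene_fits["condition"] == ref_condition]
    stim = gene_fits[gene_fits["condition"] == stim_condition]
    if ref.empty or stim.empty:
        raise ValidationError(
            f"empty group for comparison {stim_condition} vs {ref_condition}")

    mean_ref = float(ref["pdui"].mean())
    mean_stim = float(stim["pdui"].mean())
    dpdui = mean_stim - mean_ref

    if len(ref) < 2 or len(stim) < 2:
        return mean_ref, mean_stim, dpdui, 1.0

    if method == "fisher":
        table = np.array([
            [round(float(ref["w_long"].sum())), round(float(ref["w_short"].sum()))],
            [round(float(stim["w_long"].sum())), round(float(stim["w_short"].sum()))],
        ])
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            p = 1.0
        else:
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    elif method == "welch":
        res = stats.ttest_ind(stim["pdui"], ref["pdui"], equal_var=False)
        p = float(res.pvalue)
        if np.isnan(p):
            p = 1.0
    else:
        raise ValidationError(f"unknown test method {method!r}")
    return mean_ref, mean_stim, dpdui, p


def call_events(
    fits_df: pd.DataFrame,
    ref_condition: str,
    stim_condition: str,
    method: str = "fisher",
    qc_keep: tuple[str, ...] = (QC_OK,),
) -> pd.DataFrame:
    """Per-gene dPDUI and raw p for one comparison batch (unadjusted)."""
    keep = fits_df[fits_df["qc_flag"].isin(qc_keep)]
    rows = []
    for gene_id, sub in keep.groupby("gene_id", sort=True):
        if not ((sub["condition"] == ref_condition).any()
                and (sub["condition"] == stim_condition).any()):
            continue
        mean_ref, mean_stim, dpdui, p = test_event(
            sub, ref_condition, stim_condition, method=method)
        rows.append({
            "gene_id": gene_id,
            "comparison": f"{stim_condition}_vs_{ref_condition}",
            "mean_pdui_ref": mean_ref,
            "mean_pdui_stim": mean_stim,
            "dpdui": dpdui,
            "p_raw": p,
        })
    return pd.DataFrame(rows, columns=["gene_id", "comparison", "mean_pdui_ref",
                                       "mean_pdui_stim", "dpdui", "p_raw"])


def adjust_and_call(
    events: pd.DataFrame,
    dpdui_threshold: float = 20.0,
    alpha: float = 0.05,
    nonchange_band: float = 3.0,
) -> pd.DataFrame:
    """BH adjustment across the batch plus the categorical call.

    shortened:    dPDUI <= -threshold and adjusted p < alpha
    lengthened:   dPDUI >= +threshold and adjusted p < alpha
    non_changing: |dPDUI| < nonchange_band and raw p > alpha
    indeterminate otherwise.
    """
    events = events.copy()
    if events.empty:
        events["p_adj"] = pd.Series(dtype=float)
        events["call"] = pd.Series(dtype=str)
        return events
    events["p_adj"] = multipletests(events["p_raw"].to_numpy(),
                                    method="fdr_bh")[1]

    dpdui = events["dpdui"].to_numpy()
    p_adj = events["p_adj"].to_numpy()
    p_raw = events["p_raw"].to_numpy()
    call = np.full(len(events), CALL_INDETERMINATE, dtype=object)
    with np.errstate(invalid="ignore"):
        call[(dpdui <= -dpdui_threshold) & (p_adj < alpha)] = CALL_SHORTENED
        call[(dpdui >= dpdui_threshold) & (p_adj < alpha)] = CALL_LENGTHENED
        call[(np.abs(dpdui) < nonchange_band) & (p_raw > alpha)] = CALL_NON_CHANGING
    call[np.isnan(dpdui)] = CALL_INDETERMINATE
    events["call"] = call
    return events
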