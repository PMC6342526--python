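"""Group summaries and the ranked-ratio AUC similarity measure.

The headline comparison between the adaxial and abaxial ratio
distributions is descriptive, not a hypothesis test: per-group mean, SD
(sample, n-1 denominator) and SEM, quartile/whisker numbers backing violin
plots, and a rank-based area-under-the-curve (AUC) similarity score. The
AUC is the normalized Mann-Whitney statistic

    AUC = P(abaxial > adaxial) + 0.5 * P(abaxial == adaxial)

over all cross pairs: 0.5 means the two distributions are identical in
rank terms, 1.0 complete separation with abaxial higher. An alternative
trapezoid construction over the two rank-normalized sorted curves is
exposed for comparison; the rank-sum form is the default and the standard
meaning of AUC for two samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["GroupStats", "AUCResult", "group_stats", "ranked_ratio_auc", "violin_summary"]


@dataclass
class GroupStats:
    """Descriptive summary of one domain's ratio distribution."""

    domain: str
    n: int
    mean: float
    sd: float
    sem: float
    single_value: bool = False  # sd undefined for n == 1; reported as 0


@dataclass
class AUCResult:
    """Ranked-ratio AUC between the two groups, plus plot-ready curves."""

    auc: float
    n_adaxial: int
    n_abaxial: int
    adaxial_curve: np.ndarray  # sorted ratios
    abaxial_curve: np.ndarray
    adaxial_rank: np.ndarray  # normalized rank in [0, 1]
    abaxial_rank: np.ndarray
    method: str = "rank-sum"


def group_stats(records_or_ratios, domain: str | None = None) -> GroupStats:
    """Mean, sample SD and SEM of a domain's ratios.

    Accepts either an array of ratios or a DataFrame / record list with
    ``ratio`` and ``domain`` fields (then ``domain`` selects the group).
    A single-value group has undefined sample SD; it is reported as 0 with
    ``single_value`` set.
    """
    ratios = _ratios_of(records_or_ratios, domain)
    if len(ratios) == 0:
        raise ValueError(f"no records in group {domain!r}")
    n = len(ratios)
    mean = float(np.mean(ratios))
    if n == 1:
        return GroupStats(domain or "", n, mean, 0.0, 0.0, single_value=True)
    sd = float(np.std(ratios, ddof=1))
    return GroupStats(domain or "", n, mean, sd, sd / np.sqrt(n))


def _ratios_of(obj, domain: str | None) -> np.ndarray:
    if isinstance(obj, pd.DataFrame):
        df = obj
        if domain is not None:
            df = df[df["domain"] == domain]
        return df["ratio"].to_numpy(dtype=float)
    if len(obj) and hasattr(obj[0], "ratio"):
        return np.array(
            [r.ratio for r in obj if domain is None or r.domain == domain], dtype=float
        )
    return np.asarray(obj, dtype=float)


def ranked_ratio_auc(
    adaxial_ratios, abaxial_ratios, method: str = "rank-sum"
) -> AUCResult:
    """AUC similarity between the two ratio distributions.

    rank-sum (default): the Mann-Whitney U of the abaxial group over all
    cross pairs, normalized by n_ab * n_ad, counting ties as half. Computed
    from midranks of the pooled sample, so ties are exact. 0.5 for
    identical multisets; antisymmetric under swapping the groups.

    trapezoid: area under the curve traced by plotting both groups' sorted
    ratios against rank normalized to [0, 1] and integrating abaxial
    quantiles against adaxial quantiles — an alternative reading kept for
    comparison only.
    """
    ad = np.asarray(adaxial_ratios, dtype=float)
    ab = np.asarray(abaxial_ratios, dtype=float)
    if len(ad) == 0 or len(ab) == 0:
        raise ValueError("both groups must be non-empty")

    if method == "rank-sum":
        pooled = np.concatenate([ab, ad])
        ranks = rankdata(pooled)  # midranks for ties
        r_ab = ranks[: len(ab)].sum()
        u_ab = r_ab - len(ab) * (len(ab) + 1) / 2.0
        auc = float(u_ab / (len(ab) * len(ad)))
    elif method == "trapezoid":
        # evaluate both empirical quantile curves on a common rank grid and
        # integrate the ROC-style curve (adaxial exceedance vs abaxial's)
        grid = np.linspace(0, 1, 512)
        q_ad = np.quantile(ad, grid)
        q_ab = np.quantile(ab, grid)
        # fraction of adaxial below each abaxial quantile
        ad_sorted = np.sort(ad)
        frac_below = np.searchsorted(ad_sorted, q_ab, side="left") / len(ad)
        auc = float(np.trapezoid(frac_below, grid))
        del q_ad
    else:
        raise ValueError(f"unknown method {method!r}")

    return AUCResult(
        auc=auc,
        n_adaxial=len(ad),
        n_abaxial=len(ab),
        adaxial_curve=np.sort(ad),
        abaxial_curve=np.sort(ab),
        adaxial_rank=(np.arange(1, len(ad) + 1) - 0.5) / len(ad),
        abaxial_rank=(np.arange(1, len(ab) + 1) - 0.5) / len(ab),
        method=method,
    )


def violin_summary(records_or_ratios, domain: str | None = None) -> dict:
    """Numbers backing a violin/box plot for one group.

    Quartiles use linear interpolation; whiskers extend to the most
    extreme data point within 1.5 x IQR of the quartiles (Tukey rule); the
    raw values are returned for jitter overlays.
    """
    ratios = _ratios_of(records_or_ratios, domain)
    if len(ratios) == 0:
        raise ValueError("empty group")
    q1, med, q3 = (float(v) for v in np.percentile(ratios, [25, 50, 75]))
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = ratios[(ratios >= lo_fence) & (ratios <= hi_fence)]
    return {
        "n": int(len(ratios)),
        "median": med,
        "q1": q1,
        "q3": q3,
        "iqr": iqr,
        "whisker_low": float(inside.min()) if len(inside) else med,
        "whisker_high": float(inside.max()) if len(inside) else med,
        "points": np.sort(ratios),
    }
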