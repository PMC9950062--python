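"""Scalar screen arithmetic: mutagenic rate, Livak fold change, percent
area, count summaries, and the scalar-endpoint test-selection tree.

These are the bookkeeping computations around the imaging pipeline:

* mutagenic rate — among embryos with a standard PCR product (S+), the
  percentage that also show a headloop PCR product (H+), i.e. carry an
  indel at the target locus; guides pass validation only above a strict
  70% threshold.
* Livak relative expression — 2^-ddCt with technical replicates averaged
  on the Ct scale before differencing against the housekeeping gene.
* percent area — fraction of ROI pixels at or above an 8-bit threshold
  (default 40), used for fluorescence (e.g. mCherry) signal.
* count summaries — per-larva mean of BrdU+ cell counts and sum of
  TUNEL+ puncta over three consecutive central sections.
* scalar endpoint comparison — D'Agostino-Pearson normality gate, then
  Welch t (both groups normal) or Mann-Whitney for two groups, and
  Kruskal-Wallis followed by Dunn's pairwise tests for more.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import RoiMask

__all__ = [
    "mutagenic_rate",
    "validation_gate",
    "pooled_rnp_concentration",
    "livak_fold_change",
    "LivakResult",
    "percent_area",
    "summarize_counts",
    "compare_scalar_endpoint",
    "EndpointResult",
    "dunn_test",
]


def mutagenic_rate(band_calls: pd.DataFrame, gene: str) -> float:
    """Percent of standard-PCR-positive embryos that are headloop-positive.

    H+/S+ semantics: embryos whose standard PCR failed (S-) are dropped
    from numerator and denominator alike.
    """
    sub = band_calls[band_calls["gene"] == gene]
    s_pos = sub[sub["standard_positive"].astype(bool)]
    if len(s_pos) == 0:
        raise ValueError(
            f"no standard-PCR-positive embryos for {gene!r}; assay uninterpretable"
        )
    h_pos = s_pos["headloop_positive"].astype(bool).sum()
    return 100.0 * float(h_pos) / float(len(s_pos))


def validation_gate(rate: float, threshold: float = 70.0) -> bool:
    """Guide validation: pass iff the mutagenic rate strictly exceeds the
    threshold (70 exactly fails)."""
    if not (0.0 <= rate <= 100.0):
        raise ValueError("mutagenic rate must lie in [0, 100]")
    return rate > threshold


def pooled_rnp_concentration(per_rnp_uM: Sequence[float]) -> float:
    """Total concentration of a pooled RNP injection mix (sum, in uM)."""
    if len(per_rnp_uM) == 0:
        raise ValueError("empty RNP list")
    if any(c <= 0 for c in per_rnp_uM):
        raise ValueError("RNP concentrations must be positive")
    return float(sum(per_rnp_uM))


@dataclass(frozen=True)
class LivakResult:
    delta_ct_control: float
    delta_ct_knockout: float
    delta_delta_ct: float
    fold_change: float
    percent_change: float  # (fold - 1) * 100; negative = decreased expression


def livak_fold_change(ct_table: pd.DataFrame) -> LivakResult:
    """Relative expression by the Livak method (2^-ddCt).

    Technical replicates are averaged on the Ct scale per group;
    dCt = mean target Ct - mean housekeeping Ct; ddCt = dCt_knockout -
    dCt_control; fold change = 2^-ddCt (knockout relative to control).
    """
    groups = set(ct_table["sample_group"])
    for required in ("control", "knockout"):
        if required not in groups:
            raise ValueError(f"Ct table is missing the {required!r} group")
    means = ct_table.groupby("sample_group")[["target_ct", "housekeeping_ct"]].mean()
    d_ctl = float(means.loc["control", "target_ct"] - means.loc["control", "housekeeping_ct"])
    d_ko = float(means.loc["knockout", "target_ct"] - means.loc["knockout", "housekeeping_ct"])
    ddct = d_ko - d_ctl
    fold = float(2.0 ** (-ddct))
    return LivakResult(
        delta_ct_control=d_ctl,
        delta_ct_knockout=d_ko,
        delta_delta_ct=ddct,
        fold_change=fold,
        percent_change=(fold - 1.0) * 100.0,
    )


def percent_area(image: np.ndarray, mask: RoiMask, threshold: int = 40) -> float:
    """Percent of ROI pixels at or above ``threshold`` (8-bit scale).

    The >= inequality realizes the screen's fixed "40/255" thresholding
    convention; pass a different threshold to change it.
    """
    if mask.pixel_count == 0:
        raise ValueError("empty ROI mask")
    rows, cols = mask.coords()
    values = np.asarray(image)[rows, cols]
    return 100.0 * float(np.count_nonzero(values >= threshold)) / mask.pixel_count


def summarize_counts(count_table: pd.DataFrame, n_sections: int = 3) -> pd.DataFrame:
    """Per-larva summary of section counts: BrdU -> mean, TUNEL -> sum.

    Every (larva, assay) pair must contribute exactly ``n_sections``
    consecutive central sections.
    """
    rows = []
    for (larva, assay), sub in count_table.groupby(["larva_id", "assay"], sort=False):
        if len(sub) != n_sections:
            raise ValueError(
                f"larva {larva!r} has {len(sub)} {assay} sections, expected {n_sections}"
            )
        counts = sub["count"].to_numpy(dtype=np.float64)
        if assay == "BrdU":
            value = float(counts.mean())
        elif assay == "TUNEL":
            value = float(counts.sum())
        else:
            raise ValueError(f"unknown assay {assay!r}; expected BrdU or TUNEL")
        rows.append({"larva_id": larva, "assay": assay, "value": value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scalar endpoint statistics


@dataclass(frozen=True)
class EndpointResult:
    test: str
    statistic: float
    p_value: float
    normality_p: dict[str, float]
    pairwise: pd.DataFrame | None = None  # Dunn results for > 2 groups


def dunn_test(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's pairwise multiple-comparison test after Kruskal-Wallis.

    Rank-sum z statistics on pooled ranks with the tie correction
    sum(t^3 - t) / (12 (N - 1)); two-sided p-values are Bonferroni-
    adjusted over all pairs (the convention of common Dunn
    implementations).
    """
    names = list(groups)
    values = [np.asarray(groups[n], dtype=np.float64) for n in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for name, v in zip(names, values):
        sizes[name] = len(v)
        mean_ranks[name] = float(ranks[start : start + len(v)].mean())
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": float(z),
                "p": float(p),
                "p_adjusted": float(min(1.0, p * n_pairs)),
            }
        )
    return pd.DataFrame(rows)


def compare_scalar_endpoint(
    groups: Mapping[str, Sequence[float]], alpha_normality: float = 0.05
) -> EndpointResult:
    """Test-selection tree for per-larva scalar endpoints.

    Two groups: D'Agostino-Pearson on each; if both look normal, Welch's
    unequal-variance t-test, otherwise Mann-Whitney U.  More than two
    groups: Kruskal-Wallis, then Dunn's pairwise tests with adjusted
    p-values.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for name, v in arrays.items():
        if len(v) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values")
    # D'Agostino-Pearson needs n >= 8 for a stable kurtosis term; smaller
    # groups fall through to the non-parametric branch.
    normality: dict[str, float] = {}
    for name, v in arrays.items():
        if len(v) >= 8:
            normality[name] = float(sps.normaltest(v).pvalue)
        else:
            normality[name] = 0.0

    if len(arrays) == 2:
        (va, vb) = arrays.values()
        if all(p > alpha_normality for p in normality.values()):
            res = sps.ttest_ind(va, vb, equal_var=False)
            return EndpointResult("welch_t", float(res.statistic), float(res.pvalue), normality)
        res = sps.mannwhitneyu(va, vb, alternative="two-sided")
        return EndpointResult("mann_whitney", float(res.statistic), float(res.pvalue), normality)

    kw = sps.kruskal(*arrays.values())
    pairwise = dunn_test(arrays)
    return EndpointResult(
        "kruskal_wallis_dunn", float(kw.statistic), float(kw.pvalue), normality, pairwise
    )
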