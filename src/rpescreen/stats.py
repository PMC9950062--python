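"""Per-degree permutation comparison of angular profiles and phenotype calls.

Knockout and control cohorts are compared per 1-degree angular bin.  The
test statistic in each bin is the difference of group medians of
per-larva bin medians (larvae, not pixels, are the exchangeable
biological replicates).  The null is built by permuting whole-larva
group labels, with the same permutation applied to every bin within a
draw so the within-larva spatial correlation structure is preserved.
When the number of distinct label assignments is small enough the full
assignment set is enumerated and p-values are exact; otherwise labels
are resampled (default 20,000 draws) with an add-one estimator that
never returns zero.

The peripheral 0-30 and 150-180 degree regions are excluded by default:
in the screen this pipeline models, ablation is confined to the central
two-thirds of the RPE arc, so the periphery is uninformative.

A phenotype is called from maximal runs of consecutive significant
(p <= alpha) same-sign bins: runs spanning strictly more than
``min_span_deg`` degrees (i.e. >= 21 one-degree bins at the default 20)
become blocks.  Blocks where knockouts are lighter (positive intensity
difference: less pigment, impaired recovery) mark positive regulators of
regeneration; darker blocks mark negative regulators.  The per-bin
alpha carries no multiplicity correction — the contiguity requirement is
the multiplicity guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import AngularProfile

__all__ = [
    "GroupComparisonResult",
    "Block",
    "PhenotypeCall",
    "compare_groups",
    "call_phenotype",
    "screen_report",
    "DEFAULT_OMIT_RANGES",
]

DEFAULT_OMIT_RANGES: tuple[tuple[float, float], ...] = ((0.0, 30.0), (150.0, 180.0))
ENUMERATION_LIMIT = 200_000
_CHUNK = 3000


@dataclass(frozen=True)
class GroupComparisonResult:
    """Per-1-degree-bin comparison of knockout vs control profiles.

    ``frame`` columns: bin_start, delta (knockout minus control, gray
    values), p, ci_low, ci_high (2.5th/97.5th percentiles of the
    permutation-null statistic), n_ctrl, n_ko, excluded.
    """

    frame: pd.DataFrame
    mode: str  # "exact" or "sampled"
    n_permutations: int  # assignments enumerated, or draws sampled
    seed: int | None

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.attrs = {}
        out.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "GroupComparisonResult":
        df = pd.read_csv(path)
        return GroupComparisonResult(frame=df, mode="loaded", n_permutations=0, seed=None)


@dataclass(frozen=True)
class Block:
    """One contiguous significant run exceeding the span criterion.

    ``start_deg`` and ``end_deg`` are the first and last significant
    degrees, both inclusive, so a run over degrees 101..121 prints as
    "101 to 121" and spans 21 one-degree bins.
    """

    start_deg: float
    end_deg: float
    direction: str  # "lighter" (delta > 0) or "darker" (delta < 0)
    span_deg: float
    min_p: float


@dataclass(frozen=True)
class PhenotypeCall:
    blocks: list[Block] = field(default_factory=list)
    classification: str = "no_phenotype"


def _profile_matrix(profiles: Sequence[AngularProfile]) -> np.ndarray:
    if not profiles:
        raise ValueError("empty profile list")
    for p in profiles:
        if p.bin_size != 1:
            raise ValueError("compare_groups requires 1-degree-bin profiles")
    return np.vstack([p.bin_medians for p in profiles])


def _omitted_bins(n_bins: int, omit: Sequence[tuple[float, float]]) -> np.ndarray:
    starts = np.arange(n_bins, dtype=np.float64)
    omitted = np.zeros(n_bins, dtype=bool)
    for lo, hi in omit:
        omitted |= (starts < hi) & (starts + 1 > lo)
    return omitted


def _group_delta(m: np.ndarray, ko_idx: np.ndarray, ctl_idx: np.ndarray, nan_safe: bool):
    med = np.nanmedian if nan_safe else np.median
    return med(m[ko_idx], axis=-2) - med(m[ctl_idx], axis=-2)


def compare_groups(
    control_profiles: Sequence[AngularProfile],
    knockout_profiles: Sequence[AngularProfile],
    n_permutations: int = 20_000,
    omit: Sequence[tuple[float, float]] = DEFAULT_OMIT_RANGES,
    min_per_group: int = 3,
    seed: int | None = None,
    enumeration_limit: int = ENUMERATION_LIMIT,
) -> GroupComparisonResult:
    """Permutation comparison of knockout vs control per angular degree.

    Two-sided p-values against the whole-larva label-permutation null;
    exact enumeration when C(n_ctrl + n_ko, n_ko) <= ``enumeration_limit``,
    otherwise ``n_permutations`` sampled label assignments (requires
    ``seed``).  Bins inside ``omit`` ranges or with fewer than
    ``min_per_group`` larvae with data per group are flagged excluded and
    carry no p-value.
    """
    if len(control_profiles) < 2 or len(knockout_profiles) < 2:
        raise ValueError("need >= 2 larvae per group")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    mc = _profile_matrix(control_profiles)
    mk = _profile_matrix(knockout_profiles)
    if mc.shape[1] != mk.shape[1]:
        raise ValueError("control and knockout profiles have different bin counts")
    n_bins = mc.shape[1]
    n_ctl, n_ko = mc.shape[0], mk.shape[0]
    n_total = n_ctl + n_ko
    m = np.vstack([mc, mk])  # larvae x bins

    n_ctrl_data = np.sum(~np.isnan(mc), axis=0)
    n_ko_data = np.sum(~np.isnan(mk), axis=0)
    excluded = (
        _omitted_bins(n_bins, omit)
        | (n_ctrl_data < min_per_group)
        | (n_ko_data < min_per_group)
    )
    informative = ~excluded
    if not informative.any():
        raise ValueError("every angular bin is excluded; nothing to compare")

    nan_safe = bool(np.isnan(m[:, informative]).any())
    obs_ctl = np.arange(n_ctl)
    obs_ko = np.arange(n_ctl, n_total)
    observed = _group_delta(m[:, informative], obs_ko, obs_ctl, nan_safe)

    n_assignments = comb(n_total, n_ko)
    exact = n_assignments <= enumeration_limit
    if not exact and seed is None:
        raise ValueError("seed is required for sampled permutation mode")

    abs_obs = np.abs(observed)
    ge_count = np.zeros(observed.shape, dtype=np.int64)
    null_samples = []
    msub = m[:, informative]

    def _accumulate(ko_idx_chunk: np.ndarray) -> None:
        # stable argsort of the membership mask: control indices first
        mask = np.zeros((len(ko_idx_chunk), n_total), dtype=bool)
        np.put_along_axis(mask, ko_idx_chunk, True, axis=1)
        order = np.argsort(mask, axis=1, kind="stable")
        ctl_chunk = order[:, :n_ctl]
        # gather per-assignment group submatrices: (chunk, group, bins)
        med = np.nanmedian if nan_safe else np.median
        d = med(msub[ko_idx_chunk], axis=1) - med(msub[ctl_chunk], axis=1)
        ge_count[:] += np.sum(np.abs(d) >= abs_obs[None, :], axis=0)
        null_samples.append(d)

    if exact:
        all_ko = np.fromiter(
            (i for c in combinations(range(n_total), n_ko) for i in c),
            dtype=np.intp,
            count=n_assignments * n_ko,
        ).reshape(n_assignments, n_ko)
        for lo in range(0, n_assignments, _CHUNK):
            _accumulate(all_ko[lo : lo + _CHUNK])
        p = ge_count / n_assignments
        mode, n_used = "exact", n_assignments
    else:
        rng = np.random.default_rng(seed)
        done = 0
        while done < n_permutations:
            take = min(_CHUNK, n_permutations - done)
            perms = np.argsort(rng.random((take, n_total)), axis=1)
            _accumulate(np.ascontiguousarray(perms[:, :n_ko]))
            done += take
        p = (1 + ge_count) / (1 + n_permutations)
        mode, n_used = "sampled", n_permutations

    null = np.concatenate(null_samples, axis=0)
    ci_low = np.percentile(null, 2.5, axis=0)
    ci_high = np.percentile(null, 97.5, axis=0)

    frame = pd.DataFrame(
        {
            "bin_start": np.arange(n_bins),
            "delta": np.nan,
            "p": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "n_ctrl": n_ctrl_data,
            "n_ko": n_ko_data,
            "excluded": excluded,
        }
    )
    frame.loc[informative, "delta"] = observed
    frame.loc[informative, "p"] = p
    frame.loc[informative, "ci_low"] = ci_low
    frame.loc[informative, "ci_high"] = ci_high
    return GroupComparisonResult(frame=frame, mode=mode, n_permutations=n_used, seed=seed)


def call_phenotype(
    result: GroupComparisonResult,
    alpha: float = 0.05,
    min_span_deg: float = 20.0,
) -> PhenotypeCall:
    """Call regulator phenotypes from contiguous significant runs.

    A run is a maximal set of consecutive non-excluded 1-degree bins with
    p <= alpha and a constant sign of the observed difference; an
    excluded, missing, non-significant, zero-difference or opposite-sign
    bin breaks it.  Runs spanning strictly more than ``min_span_deg``
    degrees become blocks.  Classification: only lighter blocks ->
    positive_regulator; only darker -> negative_regulator; both ->
    mixed; none -> no_phenotype.
    """
    df = result.frame.sort_values("bin_start")
    bin_width = 1.0
    blocks: list[Block] = []
    run: list[tuple[float, float, float]] = []  # (bin_start, delta, p)

    def _flush() -> None:
        if not run:
            return
        span = len(run) * bin_width
        if span > min_span_deg:
            deltas = [d for _, d, _ in run]
            blocks.append(
                Block(
                    start_deg=run[0][0],
                    end_deg=run[-1][0],
                    direction="lighter" if deltas[0] > 0 else "darker",
                    span_deg=span,
                    min_p=min(p for _, _, p in run),
                )
            )
        run.clear()

    prev_start = None
    for row in df.itertuples(index=False):
        significant = (
            not row.excluded
            and np.isfinite(row.p)
            and row.p <= alpha
            and np.isfinite(row.delta)
            and row.delta != 0
        )
        contiguous = prev_start is not None and row.bin_start == prev_start + bin_width
        if significant and run and contiguous and (row.delta > 0) == (run[-1][1] > 0):
            run.append((row.bin_start, row.delta, row.p))
        else:
            _flush()
            if significant:
                run.append((row.bin_start, row.delta, row.p))
        prev_start = row.bin_start
    _flush()

    directions = {b.direction for b in blocks}
    if not blocks:
        classification = "no_phenotype"
    elif directions == {"lighter"}:
        classification = "positive_regulator"
    elif directions == {"darker"}:
        classification = "negative_regulator"
    else:
        classification = "mixed"
    return PhenotypeCall(blocks=blocks, classification=classification)


def screen_report(calls: Mapping[str, PhenotypeCall]) -> pd.DataFrame:
    """One summary row per gene: classification, block intervals, min p."""
    if not calls:
        raise ValueError("screen_report needs at least one gene")
    rows = []
    for gene, call in calls.items():
        intervals = "; ".join(
            f"{b.start_deg:g} to {b.end_deg:g} angular degrees ({b.direction})"
            for b in call.blocks
        )
        min_p = min((b.min_p for b in call.blocks), default=np.nan)
        rows.append(
            {
                "gene": gene,
                "classification": call.classification,
                "blocks": intervals,
                "min_p": min_p,
            }
        )
    return pd.DataFrame(rows)
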