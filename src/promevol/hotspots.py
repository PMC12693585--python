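"""Promoter hotspot scores: sliding event score Se, d, and PhyloP-based d^P.

Se smooths 0/1 event codes (or summed event counts) with a centered
five-base window. The promoter score d is the percentage of events in a
350-nt promoter region whose Se strictly exceeds the control-group mean
Se (Se^C). d^P replaces events with per-base conservation scores: the
percentage of positions whose PhyloP value falls strictly below the
control-group mean (p^C). Group differences are tested with unpaired
t-tests (mean conservation) and 2x2 chi-squared tests on the d counts,
Bonferroni-corrected within a family; Benjamini-Hochberg is used for the
expression-fraction family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import EventTally, EventVector
from .genomic import offset_index

#: default 350-nt promoter region: offsets [-380, -31], immediately
#: upstream of a TATA box estimated at -30 relative to the TSS
DEFAULT_REGION = (-380, -31)


@dataclass
class SeProfile:
    """Centered sliding-window event score per reference offset."""

    unit: str
    window: int
    offsets: np.ndarray
    se: np.ndarray
    n_pairs: int = 1


@dataclass
class DScore:
    """Percent of events in the region whose Se exceeds the control baseline."""

    unit: str
    region: tuple[int, int]
    se_baseline: float
    n_events: int
    n_exceeding: int
    d: float
    defined: bool = True  # False when the region holds no events


@dataclass
class PhyloPDScore:
    """Percent of region positions with conservation below the control mean."""

    unit: str
    region: tuple[int, int]
    p_baseline: float
    n_positions: int
    n_below: int
    d_p: float


def _counts_of(events) -> tuple[str, np.ndarray, np.ndarray, int]:
    if isinstance(events, EventVector):
        return events.gene, events.offsets, events.bits.astype(int), 1
    if isinstance(events, EventTally):
        return events.group, events.offsets, events.counts, events.n_pairs
    raise TypeError("expected an EventVector or EventTally")


def sliding_event_score(events, window: int = 5) -> SeProfile:
    """Se: event counts summed over a centered window, truncated at the ends."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    unit, offsets, counts, n_pairs = _counts_of(events)
    se = np.convolve(counts.astype(float), np.ones(window), mode="same")
    return SeProfile(unit=unit, window=window, offsets=offsets, se=se, n_pairs=n_pairs)


def control_baseline(control_profiles: list[SeProfile], region: tuple[int, int]) -> float:
    """Se^C: global mean of all control Se values within the region."""
    if not control_profiles:
        raise ValueError("need at least one control profile")
    chunks = []
    for prof in control_profiles:
        mask = offset_index(prof.offsets, *region)
        if mask.any():
            chunks.append(prof.se[mask])
    if not chunks:
        raise ValueError("no control profile covers the region")
    return float(np.concatenate(chunks).mean())


def d_score(
    profile: SeProfile,
    events,
    se_baseline: float,
    region: tuple[int, int] = DEFAULT_REGION,
    d_mode: str = "events",
) -> DScore:
    """d: 100 x (events with Se > Se^C) / (events in region).

    ``d_mode='events'`` (default) counts events at positions whose Se
    strictly exceeds the baseline, guaranteeing d in [0, 100].
    ``d_mode='positions'`` instead counts every region position with
    Se > Se^C in the numerator (may exceed 100). When the region holds no
    events, d is 0 and flagged undefined.
    """
    if d_mode not in ("events", "positions"):
        raise ValueError("d_mode must be 'events' or 'positions'")
    unit, offsets, counts, _ = _counts_of(events)
    if not np.array_equal(offsets, profile.offsets):
        raise ValueError("profile and events must share the offset range")
    mask = offset_index(offsets, *region)
    if not mask.any():
        raise ValueError(f"region {region} outside profile offsets")
    n_events = int(counts[mask].sum())
    exceeds = profile.se[mask] > se_baseline
    if d_mode == "events":
        n_exceeding = int(counts[mask][exceeds].sum())
    else:
        n_exceeding = int(exceeds.sum())
    if n_events == 0:
        return DScore(unit, region, se_baseline, 0, n_exceeding, 0.0, defined=False)
    return DScore(unit, region, se_baseline, n_events, n_exceeding,
                  100.0 * n_exceeding / n_events)


def phylop_baseline(control_tracks: list[np.ndarray], offsets: np.ndarray,
                    region: tuple[int, int] = DEFAULT_REGION) -> float:
    """p^C: mean conservation of the control group over the promoter region."""
    mask = offset_index(offsets, *region)
    vals = np.concatenate([np.asarray(t, dtype=float)[mask] for t in control_tracks])
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no control conservation values in the region")
    return float(vals.mean())


def phylop_d_score(
    values: np.ndarray,
    offsets: np.ndarray,
    p_baseline: float,
    region: tuple[int, int] = DEFAULT_REGION,
    unit: str = "gene",
) -> PhyloPDScore:
    """d^P: 100 x (positions with p < p^C) / (positions in the region).

    NaN values in the region are excluded from both counts with a warning.
    """
    values = np.asarray(values, dtype=float)
    offsets = np.asarray(offsets)
    if values.shape != offsets.shape:
        raise ValueError("values and offsets must align")
    mask = offset_index(offsets, *region)
    if not mask.any():
        raise ValueError(f"region {region} outside track offsets")
    region_vals = values[mask]
    missing = np.isnan(region_vals)
    if missing.any():
        import warnings

        warnings.warn(f"{unit}: {missing.sum()} missing conservation values excluded",
                      stacklevel=2)
        region_vals = region_vals[~missing]
    n_positions = int(region_vals.size)
    if n_positions == 0:
        raise ValueError("no usable conservation values in the region")
    n_below = int((region_vals < p_baseline).sum())
    return PhyloPDScore(unit, region, p_baseline, n_positions, n_below,
                        100.0 * n_below / n_positions)


def metagene_profile(tracks: list[np.ndarray]) -> np.ndarray:
    """Per-offset mean signal across genes aligned at their TSSs (NaN-skipping)."""
    if not tracks:
        raise ValueError("need at least one track")
    arr = np.vstack([np.asarray(t, dtype=float) for t in tracks])
    with np.errstate(invalid="ignore"):
        return np.nanmean(arr, axis=0)


def compare_means_ttest(group_a, group_b) -> tuple[float, float]:
    """Two-sided unpaired Student t-test on two groups of per-gene values."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("degenerate (zero) pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def compare_groups_chi2(
    n_exceeding_a: int,
    n_events_a: int,
    n_exceeding_b: int,
    n_events_b: int,
    n_comparisons: int = 1,
) -> tuple[float, float, float]:
    """2x2 chi-squared (no continuity correction) on exceeding vs not, by group.

    Returns (chi2, raw p, Bonferroni p = min(1, p x n_comparisons)).
    """
    for name, val in (("n_exceeding_a", n_exceeding_a), ("n_events_a", n_events_a),
                      ("n_exceeding_b", n_exceeding_b), ("n_events_b", n_events_b)):
        if val < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_exceeding_a > n_events_a or n_exceeding_b > n_events_b:
        raise ValueError("exceeding counts cannot surpass totals")
    table = np.array([
        [n_exceeding_a, n_events_a - n_exceeding_a],
        [n_exceeding_b, n_events_b - n_exceeding_b],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-squared test requires nonzero marginals")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), float(min(1.0, p * n_comparisons))
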