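"""Positional clustering of sequence-change events via the G function.

For n events at sorted alignment positions x_1 < ... < x_n in an alignment
of length L, G_k = k/n - (x_k + 1)/L measures the excess of the relative
event count over the relative position. Stretches where G climbs mark
regions accumulating events faster than a uniform scatter. The maximal
climb max_{i<j} (G_j - G_i) is tested against a Monte Carlo null built by
sampling n distinct sites uniformly without replacement along the
alignment; significant stretches are masked and the remaining events are
retested against a null re-simulated at the reduced n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GSeries:
    """G-function values at each of n sorted event positions."""

    alignment_length: int
    positions: np.ndarray  # sorted, unique, 0-based alignment columns
    g: np.ndarray  # G_k per event, k = 1..n
    delta_g: np.ndarray  # consecutive differences, length n - 1

    @property
    def n_events(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class HotspotCall:
    """A significant stretch of events (0-based event indices, half-open span)."""

    start_event: int
    end_event: int
    span: tuple[int, int]  # alignment columns [start, end)
    observed_delta: float
    p_empirical: float
    n_resamples: int


@dataclass
class NullDistribution:
    """Monte Carlo null of max-stretch deltas for a given (n, L)."""

    n: int
    L: int
    deltas: np.ndarray = field(repr=False)

    @property
    def n_resamples(self) -> int:
        return len(self.deltas)


def g_function(positions, L: int) -> GSeries:
    """G_k = k/n - (x_k + 1)/L for sorted unique 0-based positions x in [0, L)."""
    x = np.asarray(positions, dtype=int)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least two event positions")
    if np.any(np.diff(x) == 0):
        raise ValueError("duplicate event positions; merge events at one site first")
    x = np.sort(x)
    if x[0] < 0 or x[-1] >= L:
        raise ValueError(f"positions must lie in [0, {L})")
    n = len(x)
    k = np.arange(1, n + 1)
    g = k / n - (x + 1) / L
    return GSeries(alignment_length=L, positions=x, g=g, delta_g=np.diff(g))


def max_stretch(gs: GSeries) -> tuple[int, int, float]:
    """The event run (i, j), i < j, maximizing G_j - G_i (the maximal climb).

    Indices are 0-based into the event list; ties broken by smaller i,
    then smaller j.
    """
    g = gs.g
    best = (-np.inf, 0, 1)
    min_val, min_idx = g[0], 0
    for j in range(1, len(g)):
        delta = g[j] - min_val
        if delta > best[0]:
            best = (delta, min_idx, j)
        if g[j] < min_val:
            min_val, min_idx = g[j], j
    delta, i, j = best
    return i, j, float(delta)


def _max_climb_rows(g: np.ndarray) -> np.ndarray:
    """Vectorised maximal climb per row of a (B, n) matrix of G values."""
    prefix_min = np.minimum.accumulate(g[:, :-1], axis=1)
    return (g[:, 1:] - prefix_min).max(axis=1)


def monte_carlo_null(
    n: int,
    L: int,
    n_resamples: int = 100_000,
    seed=None,
    chunk: int = 4000,
) -> NullDistribution:
    """Null max-stretch deltas from n sites sampled without replacement in [0, L).

    Reproducible for a given seed (or numpy Generator). Computed in chunks
    to bound memory at large n_resamples.
    """
    if not (2 <= n <= L):
        raise ValueError(f"need 2 <= n <= L, got n={n}, L={L}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    deltas = np.empty(n_resamples)
    k = np.arange(1, n + 1) / n
    done = 0
    while done < n_resamples:
        b = min(chunk, n_resamples - done)
        u = rng.random((b, L))
        pos = np.argpartition(u, n - 1, axis=1)[:, :n]
        pos.sort(axis=1)
        g = k[None, :] - (pos + 1) / L
        deltas[done : done + b] = _max_climb_rows(g)
        done += b
    return NullDistribution(n=n, L=L, deltas=deltas)


def empirical_p(observed: float, null: NullDistribution) -> float:
    """(1 + #{null >= observed}) / (1 + B); never exactly zero."""
    b = int((null.deltas >= observed).sum())
    return (1 + b) / (1 + null.n_resamples)


def call_hotspots(
    gs: GSeries,
    null: NullDistribution,
    alpha: float = 0.05,
    seed=None,
    max_calls: int = 20,
) -> list[HotspotCall]:
    """Iteratively test, mask and retest maximal climbs of the G function.

    The maximal stretch is scored against the supplied null; if its
    empirical p-value is <= alpha the stretch is reported, its events are
    masked, and the procedure recurses on the remaining events against a
    null re-simulated (same resample count, same L) at the reduced n.
    Calls are returned sorted by span start.
    """
    if null.n != gs.n_events or null.L != gs.alignment_length:
        raise ValueError(
            f"null distribution is for (n={null.n}, L={null.L}), "
            f"series has (n={gs.n_events}, L={gs.alignment_length})"
        )
    if alpha <= 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calls: list[HotspotCall] = []
    positions = gs.positions
    current_null = null
    while len(positions) >= 2 and len(calls) < max_calls:
        series = g_function(positions, gs.alignment_length)
        i, j, delta = max_stretch(series)
        p = empirical_p(delta, current_null)
        if p > alpha:
            break
        calls.append(
            HotspotCall(
                start_event=i,
                end_event=j,
                span=(int(positions[i]), int(positions[j]) + 1),
                observed_delta=delta,
                p_empirical=p,
                n_resamples=current_null.n_resamples,
            )
        )
        positions = np.concatenate([positions[:i], positions[j + 1 :]])
        if len(positions) < 2:
            break
        current_null = monte_carlo_null(
            len(positions), gs.alignment_length, current_null.n_resamples, seed=rng
        )
    return sorted(calls, key=lambda c: c.span[0])
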