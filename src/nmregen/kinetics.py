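"""Division timing: waves, generation-resolved cycle lengths and
two-segment change-point regression.

Regenerating neuromasts divide in transient synchronized waves.  The wave
structure is read off a Gaussian-kernel-smoothed division-time density;
cycle lengths are grouped by the dividing cell's generation; and the
relation of cycle length to regeneration time (or organ size) is summarized
by a continuous two-segment ("broken stick") least-squares regression whose
change point is found by exhaustive search over all admissible breakpoints,
so the fit is deterministic and exactly reproducible.

The two-segment model is

    y = a + b1 * x                      for x <= c
    y = a + b1 * c + b2 * (x - c)       for x >  c

with the change point c restricted so that both segments keep at least
``min_points`` observations.  Candidates are the midpoints between
consecutive distinct sorted x values; for each candidate the model is linear
in (a, b1, b2) and solved by least squares.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .lineage import LineageForest

__all__ = [
    "DivisionHistogram",
    "division_histogram",
    "detect_wave_peaks",
    "cycle_lengths_by_generation",
    "TwoSegmentFit",
    "two_segment_fit",
    "sample_two_segment",
]


@dataclasses.dataclass
class DivisionHistogram:
    """Binned division counts plus a kernel-smoothed density."""

    bin_edges: np.ndarray
    counts: np.ndarray
    grid: np.ndarray  # hpi, fine evaluation grid for the density
    density: np.ndarray  # per-hour density, integrates to ~1
    bandwidth_h: float
    n: int


def division_histogram(
    times: Sequence[float] | np.ndarray,
    bin_width_h: float = 1.0,
    bandwidth_h: float = 1.0,
    t_range: tuple[float, float] | None = None,
    grid_step_h: float = 0.25,
) -> DivisionHistogram:
    """Histogram of division times with a Gaussian-smoothed density."""
    if bin_width_h <= 0:
        raise ValueError("bin_width_h must be positive")
    times = np.asarray(times, dtype=float)
    if t_range is None:
        if times.size:
            t_range = (float(times.min()) - 2.0, float(times.max()) + 2.0)
        else:
            t_range = (0.0, 1.0)
    t0, t1 = t_range
    edges = np.arange(t0, t1 + bin_width_h, bin_width_h)
    counts, _ = np.histogram(times, bins=edges)
    grid = np.arange(t0, t1 + grid_step_h / 2, grid_step_h)
    if times.size:
        z = (grid[:, None] - times[None, :]) / bandwidth_h
        density = np.exp(-0.5 * z**2).sum(axis=1)
        density /= times.size * bandwidth_h * np.sqrt(2 * np.pi)
    else:
        density = np.zeros_like(grid)
    return DivisionHistogram(
        bin_edges=edges,
        counts=counts,
        grid=grid,
        density=density,
        bandwidth_h=bandwidth_h,
        n=int(times.size),
    )


def detect_wave_peaks(
    hist: DivisionHistogram, prominence_fraction: float = 0.10
) -> np.ndarray:
    """Times (hpi) of division-wave peaks, sorted ascending.

    A wave is a local maximum of the smoothed density with prominence at
    least ``prominence_fraction`` of the global maximum.  Flat densities
    yield an empty array.
    """
    d = hist.density
    if d.size == 0 or d.max() <= 0:
        return np.empty(0)
    idx, _ = find_peaks(d, prominence=prominence_fraction * d.max())
    return hist.grid[idx]


def cycle_lengths_by_generation(
    forests: LineageForest | Iterable[LineageForest],
    parent_class: str | None = "S",
) -> pd.DataFrame:
    """Completed cell-cycle lengths grouped by the parent's generation.

    For non-founders the cycle runs from birth to own division; for
    founders it runs from the recording start.  Returns one row per
    generation with n, mean, sd, median and iqr.  ``parent_class``
    restricts to divisions of that class (default sustentacular; None
    keeps all).
    """
    forests = [forests] if isinstance(forests, LineageForest) else list(forests)
    lengths: dict[int, list[float]] = {}
    for f in forests:
        for ev in f.divisions():
            if parent_class is not None and ev.parent_class != parent_class:
                continue
            cyc = f.cycle_length(ev.lineage_id, ev.parent_index)
            lengths.setdefault(ev.generation, []).append(cyc)
    if not lengths:
        raise ValueError("no completed cycles")
    rows = []
    for gen in sorted(lengths):
        arr = np.asarray(lengths[gen])
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        rows.append(
            {
                "generation": gen,
                "n": arr.size,
                "mean_h": arr.mean(),
                "sd_h": arr.std(ddof=1) if arr.size > 1 else 0.0,
                "median_h": med,
                "iqr_h": q3 - q1,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["lengths"] = {g: np.asarray(v) for g, v in lengths.items()}
    return df


@dataclasses.dataclass
class TwoSegmentFit:
    """A continuous two-segment least-squares fit."""

    change_point: float
    intercept: float
    slope1: float
    slope2: float
    sse: float
    n_left: int
    n_right: int
    single_line_sse: float
    single_line_slope: float
    single_line_intercept: float
    degenerate: bool  # True when the break adds nothing over a single line

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (
            self.intercept
            + self.slope1 * np.minimum(x, self.change_point)
            + self.slope2 * np.maximum(x - self.change_point, 0.0)
        )


def _lstsq_sse(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def two_segment_fit(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    min_points: int = 5,
) -> TwoSegmentFit:
    """Fit the continuous two-segment model by exhaustive breakpoint search.

    Candidate change points are the distinct interior x values and the
    midpoints between consecutive distinct sorted x values, subject to at
    least ``min_points`` observations on each side.  The fit with the smallest total squared error wins; ties go to
    the earliest candidate.  Raises ``ValueError`` with fewer than
    2 * min_points observations or no admissible candidate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2 * min_points:
        raise ValueError(f"need at least {2 * min_points} points, got {n}")

    ones = np.ones(n)
    beta_line, sse_line = _lstsq_sse(np.column_stack([ones, x]), y)

    ux = np.unique(x)
    # candidate breaks: the sample points themselves plus the midpoints
    # between neighbors, so a kink lying exactly on a sample is recovered
    # exactly while ties between samples land on the midpoint
    candidates = np.unique(np.concatenate([ux[1:-1], (ux[:-1] + ux[1:]) / 2.0]))
    best = None
    for c in candidates:
        n_left = int((x <= c).sum())
        n_right = n - n_left
        if n_left < min_points or n_right < min_points:
            continue
        X = np.column_stack([ones, x, np.maximum(x - c, 0.0)])
        beta, sse = _lstsq_sse(X, y)
        if best is None or sse < best[1] - 1e-12:
            best = (c, sse, beta, n_left, n_right)
    if best is None:
        raise ValueError("no admissible change-point candidate")
    c, sse, beta, n_left, n_right = best
    a, b1, db = beta
    # guard: the two-segment model nests the line, so sse <= sse_line up to
    # round-off; clip tiny negative improvements
    sse = min(sse, sse_line)
    degenerate = (sse_line - sse) <= 1e-9 * max(1.0, sse_line)
    return TwoSegmentFit(
        change_point=float(c),
        intercept=float(a),
        slope1=float(b1),
        slope2=float(b1 + db),
        sse=sse,
        n_left=n_left,
        n_right=n_right,
        single_line_sse=sse_line,
        single_line_slope=float(beta_line[1]),
        single_line_intercept=float(beta_line[0]),
        degenerate=bool(degenerate),
    )


def sample_two_segment(
    n: int,
    change_point: float,
    pre_level: float,
    slope1: float,
    slope2: float,
    noise_sd: float,
    x_range: tuple[float, float],
    rng: np.random.Generator,
    integer_x: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x, y) pairs from the continuous two-segment model.

    ``pre_level`` is the mean response at the left edge of ``x_range``.
    With ``integer_x`` the abscissae are uniform integers (e.g. cell
    counts), otherwise uniform reals (e.g. hpi).
    """
    lo, hi = x_range
    if integer_x:
        x = rng.integers(int(lo), int(hi) + 1, size=n).astype(float)
    else:
        x = rng.uniform(lo, hi, size=n)
    a = pre_level - slope1 * lo
    y = (
        a
        + slope1 * np.minimum(x, change_point)
        + slope2 * np.maximum(x - change_point, 0.0)
        + rng.normal(0.0, noise_sd, size=n)
    )
    return x, y
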