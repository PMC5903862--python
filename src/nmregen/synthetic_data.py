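"""Agent-based generator of regenerating-neuromast track tables.

The generator emulates the study conditions of the tracked regeneration
cohort: 15 independent recordings, each starting 4 hpi from 4-10 surviving
founder cells (2-3 mantle at the organ rim, 2-7 sustentacular inside),
imaged every 15 min for 65-100 h.  Sustentacular founders divide around
19 +/- 6 hpi (coordinated within an experiment), dividing mantle founders
around 27 +/- 5 hpi with probability 16/30.  Subsequent sustentacular cell
cycles last ~Normal(11, 3) h and lengthen past a change point (47 hpi by
default, or 24 cells in "size" mode).  Division fates follow the observed
category marginals (SS 0.78, HH 0.16, MM 0.03, SM 0.03) with the observed
spatial structure: HH divisions central, appearing only after hair-cell
onset (48 hpi) and biased dorsoventrally late; MM/SM divisions peripheral
and suppressed near existing mantle cells.  Mantle lineages divide only MM
(at most two rounds); hair daughters are terminal.

Fate assignment uses per-experiment quota balancing: each category's weight
is the product of its remaining target count and a spatial eligibility
factor.  The quota keeps the realized category marginals at their
configured values regardless of when divisions happen (the hair-cell onset
forbids early HH, so the deficit is repaid by later central divisions),
while the eligibility factors decide *which* division receives which
category - producing the central-HH / peripheral-MM,SM pattern without
distorting the marginals.

Geometry: daughters appear one frame after the division at the parent's
last position +/- a Normal(0, 3 um) displacement per axis (mirrored);
cells then perform a Normal(0, 0.4 um) per-axis random walk per frame,
contained inside the organ radius R(t) = R0 * sqrt(N(t)/N0) (constant
areal density; R0 = 20 um).

Division pressure relaxes as the organ regrows: sustentacular daughters
become quiescent with a probability that ramps up with the cell count, and
divisions scheduled after 60 hpi are retained preferentially in the dorsal
and ventral sectors, restoring the homeostatic polar proliferative
territories.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .track_io import ExperimentManifest, TrackTable, validate_tracks

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "generate_experiment",
    "generate_cohort",
    "null_variant",
]

_CATEGORIES = ("SS", "HH", "MM", "SM")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """All parameters of the synthetic regeneration generator."""

    # cohort
    n_experiments: int = 15
    seed: int = 0
    # recording
    start_hpi: float = 4.0
    frame_interval_h: float = 0.25
    duration_h_range: tuple[float, float] = (65.0, 100.0)
    # founders
    n_mantle_founders: tuple[int, int] = (2, 3)  # inclusive range
    n_sustentacular_founders: tuple[int, int] = (2, 7)
    # timing (hpi / h)
    s_first_division_mean_hpi: float = 19.0
    s_first_division_sd_h: float = 6.0
    s_first_division_within_sd_h: float = 4.0  # within-experiment coordination
    m_division_probability: float = 16.0 / 30.0
    m_first_division_mean_hpi: float = 27.0
    m_first_division_sd_h: float = 5.0
    m_second_round_probability: float = 0.1
    cycle_mean_h: float = 11.0
    cycle_sd_h: float = 3.0
    cycle_within_sd_h: float = 2.2  # jitter around the per-experiment wave
    cycle_min_h: float = 4.0
    # cycle lengthening past the change point
    lengthening_mode: str = "time"  # "time", "size" or "both"
    time_change_point_hpi: float = 47.0
    time_slope_h_per_h: float = 1.0
    size_change_point_cells: int = 24
    size_slope_h_per_cell: float = 1.5
    lengthening_extra_sd_h: float = 2.0
    # fates
    fate_probabilities: tuple[float, float, float, float] = (0.78, 0.16, 0.03, 0.03)
    hair_onset_hpi: float = 48.0
    dv_bias_onset_hpi: float = 60.0
    spatial_fate_modulation: bool = True
    # quiescence ramp: P(daughter stops cycling) grows linearly from 0 at
    # ramp_start cells to ramp_max at ramp_end cells
    quiescence_ramp_cells: tuple[int, int] = (11, 25)
    quiescence_max: float = 0.95
    # geometry (um)
    initial_radius_um: float = 20.0
    daughter_displacement_sd_um: float = 3.0
    random_walk_sd_um: float = 0.4

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        p = self.fate_probabilities
        if len(p) != 4 or any(q < 0 for q in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("fate_probabilities must be 4 non-negatives summing to 1")
        if self.lengthening_mode not in {"time", "size", "both"}:
            raise ValueError(f"bad lengthening_mode {self.lengthening_mode!r}")
        if not 0 <= self.m_division_probability <= 1:
            raise ValueError("m_division_probability must be in [0, 1]")
        if self.duration_h_range[0] > self.duration_h_range[1]:
            raise ValueError("bad duration range")
        if self.frame_interval_h <= 0 or self.initial_radius_um <= 0:
            raise ValueError("frame interval and radius must be positive")


def null_variant(config: SimulationConfig) -> SimulationConfig:
    """Toggle the spatial fate structure off (or back on).

    With modulation off, division categories are drawn from the base
    probabilities independently of position and time (including the
    hair-cell onset gate, since a time-gated HH would still be learnable
    from the absolute-time feature), and the position-dependent parts of
    division pressure (central persistence, late dorsoventral territories)
    are replaced by their position-independent averages.  The marginal fate
    probabilities are unchanged.  Applying the toggle twice returns the
    original config.
    """
    return dataclasses.replace(
        config, spatial_fate_modulation=not config.spatial_fate_modulation
    )


@dataclasses.dataclass
class GroundTruth:
    """Generator-side record of what the tracks encode."""

    experiment_id: str
    seed: int
    clone_types: dict[int, str]  # lineage_id -> clone type
    division_categories: dict[tuple[int, int], str]  # (lineage, parent) -> category
    cell_classes: dict[tuple[int, int], str]  # (lineage, node) -> class
    config: SimulationConfig


@dataclasses.dataclass
class SimulatedExperiment:
    table: TrackTable
    manifest: ExperimentManifest
    truth: GroundTruth


@dataclasses.dataclass
class _Cell:
    lineage: int
    node: int
    cls: str
    birth: float
    x: float
    y: float
    division_time: float | None = None  # scheduled, None = never
    founder_class: str = "S"


def _snap(t: float, start: float, dt: float) -> float:
    return start + round((t - start) / dt) * dt


class _FateQuota:
    """Per-experiment category quota with spatial eligibility."""

    def __init__(self, probs: tuple[float, ...], modulated: bool):
        self.probs = np.asarray(probs, dtype=float)
        self.counts = np.zeros(4)
        self.modulated = modulated

    def draw(
        self,
        rng: np.random.Generator,
        t: float,
        radial_rank: float,
        theta: float,
        n_mantle_near: int,
        cfg: SimulationConfig,
    ) -> str:
        """Draw a category for a division at radial rank ``radial_rank``.

        ``radial_rank`` is the fraction of current cells lying nearer the
        organ center than the dividing cell - a scale-free measure of how
        peripheral the division is.
        """
        if not self.modulated:
            # null model: independent draws from the base probabilities,
            # with no positional, temporal or sequential structure at all
            idx = int(rng.choice(4, p=self.probs))
            self.counts[idx] += 1
            return _CATEGORIES[idx]

        n = self.counts.sum()
        deficit = np.maximum(self.probs * (n + 1) - self.counts, 0.0)
        w = deficit + 0.05 * self.probs  # floor keeps every category reachable

        # spatial eligibility in [0, 1]: how well each category fits this
        # location; SS fits everywhere, HH the center (dorsoventrally late),
        # MM/SM the mantle-poor periphery
        s = np.ones(4)
        if t < cfg.hair_onset_hpi:
            s[1] = 0.0
        else:
            # hair fate is restricted to the central macula; once hair
            # production starts, the deep center favors differentiation
            # over self-renewal
            if radial_rank <= 0.5:
                s[1] = 0.85
            else:
                s[1] = 0.85 * max(0.85 - radial_rank, 0.0) / 0.35
            s[0] = 0.4 + 0.6 * min(radial_rank / 0.5, 1.0)
            if t >= cfg.dv_bias_onset_hpi:
                s[1] *= min(0.25 + 1.5 * math.sin(math.radians(theta)) ** 2, 1.0)
        # mantle fate only in the perimetral band, damped near existing
        # mantle cells
        s[2] = s[3] = max(radial_rank - 0.55, 0.0) / 0.45 / (
            1.0 + 0.3 * n_mantle_near
        )

        # quota proposes (keeping the marginals on target), the location
        # disposes: rejected categories keep their deficit and wait for a
        # division somewhere they fit.  SS is always eligible, so the loop
        # terminates.
        live = w.copy()
        while True:
            idx = int(rng.choice(4, p=live / live.sum()))
            if rng.uniform() < s[idx]:
                break
            live[idx] = 0.0
            if live.sum() <= 0:
                idx = 0
                break
        self.counts[idx] += 1
        return _CATEGORIES[idx]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float
) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > low:
            return v
    return low + abs(rng.normal(0.0, sd))  # pathological parameters


def generate_experiment(
    config: SimulationConfig, seed: int, experiment_id: str | None = None
) -> SimulatedExperiment:
    """Simulate one recording; deterministic for a fixed (config, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    exp_id = experiment_id or f"sim{seed:04d}"
    start = config.start_hpi
    dt = config.frame_interval_h
    duration = rng.uniform(*config.duration_h_range)
    n_frames = int(math.floor(duration / dt))
    end = start + n_frames * dt
    last_division_frame = end - dt  # daughters must appear within the movie

    n_m = int(rng.integers(config.n_mantle_founders[0], config.n_mantle_founders[1] + 1))
    n_s = int(
        rng.integers(
            config.n_sustentacular_founders[0], config.n_sustentacular_founders[1] + 1
        )
    )
    r0 = config.initial_radius_um

    cells: list[_Cell] = []
    # per-experiment wave anchor for coordinated founder divisions
    wave0 = _truncated_normal(
        rng,
        config.s_first_division_mean_hpi,
        math.sqrt(
            max(config.s_first_division_sd_h**2 - config.s_first_division_within_sd_h**2, 0.0)
        ),
        start + dt,
    )
    lineage = 0
    for _ in range(n_s):
        lineage += 1
        r = 0.7 * r0 * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        t_div = _snap(
            max(wave0 + rng.normal(0, config.s_first_division_within_sd_h), start + dt),
            start,
            dt,
        )
        cells.append(
            _Cell(
                lineage,
                1,
                "S",
                start,
                r * math.cos(th),
                r * math.sin(th),
                t_div if t_div <= last_division_frame else None,
                founder_class="S",
            )
        )
    for _ in range(n_m):
        lineage += 1
        r = r0 * (0.85 + 0.15 * rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        t_div = None
        if rng.uniform() < config.m_division_probability:
            t = _snap(
                _truncated_normal(
                    rng,
                    config.m_first_division_mean_hpi,
                    config.m_first_division_sd_h,
                    start + dt,
                ),
                start,
                dt,
            )
            if t <= last_division_frame:
                t_div = t
        cells.append(
            _Cell(
                lineage,
                1,
                "M",
                start,
                r * math.cos(th),
                r * math.sin(th),
                t_div,
                founder_class="M",
            )
        )

    n_founders = n_s + n_m
    quota = _FateQuota(config.fate_probabilities, config.spatial_fate_modulation)
    # per-experiment, per-generation wave spacing for coordinated cycles
    spacing_between_sd = math.sqrt(
        max(config.cycle_sd_h**2 - config.cycle_within_sd_h**2, 0.0)
    )
    gen_spacing = {
        g: rng.normal(config.cycle_mean_h, spacing_between_sd) for g in range(1, 16)
    }

    def schedule_daughter_division(
        birth: float, generation: int, n_now: int, radial_rank: float
    ) -> float | None:
        """Scheduled division time for a new sustentacular daughter.

        Division pressure decays as the organ regrows, preferentially at
        the periphery: central progenitors keep cycling longest, restoring
        the late, central hair-cell production.
        """
        lo, hi = config.quiescence_ramp_cells
        q = config.quiescence_max * min(max((n_now - lo) / (hi - lo), 0.0), 1.0)
        if config.spatial_fate_modulation:
            # central progenitors never quiesce; the rim settles first
            q *= min(radial_rank / 0.6, 1.0)
        else:
            # null model: position-independent quiescence with roughly the
            # same population-average pressure
            q *= 0.85
        if rng.uniform() < q:
            return None
        base = gen_spacing.get(generation, config.cycle_mean_h) + rng.normal(
            0.0, config.cycle_within_sd_h
        )
        cycle = max(base, config.cycle_min_h)
        extra = 0.0
        if config.lengthening_mode in {"time", "both"}:
            extra += config.time_slope_h_per_h * max(
                birth - config.time_change_point_hpi, 0.0
            )
        if config.lengthening_mode in {"size", "both"}:
            extra += config.size_slope_h_per_cell * max(
                n_now - config.size_change_point_cells, 0
            )
        if extra > 0:
            extra = max(extra + rng.normal(0.0, config.lengthening_extra_sd_h), 0.0)
        t = _snap(birth + cycle + extra, start, dt)
        t = max(t, birth + dt)
        return t if t <= last_division_frame else None

    rows: list[tuple] = []
    truth_categories: dict[tuple[int, int], str] = {}
    t = start
    # organ radius actually containing the cells; expands smoothly toward
    # r0 * sqrt(N / N0) as the tissue regrows
    organ_radius = r0
    for _frame in range(n_frames + 1):
        n_now = len(cells)
        for c in cells:
            rows.append((exp_id, c.lineage, c.node, t, c.x, c.y, 0.0, c.cls))

        # fire divisions whose scheduled time is this frame
        dividing = [c for c in cells if c.division_time is not None
                    and abs(c.division_time - t) < dt / 2]
        newborn: list[_Cell] = []
        if dividing:
            max_radius = max(math.hypot(o.x, o.y) for o in cells)
        for c in dividing:
            r = math.hypot(c.x, c.y)
            theta = math.degrees(math.atan2(c.y, c.x)) % 360.0
            # radial position relative to the currently furthest cell -- the
            # same normalization the downstream feature extraction uses
            radial_rank = min(r / max_radius, 1.0) if max_radius > 0 else 0.0
            if (
                config.spatial_fate_modulation
                and t >= config.dv_bias_onset_hpi
                and rng.uniform() > 0.25 + 0.75 * math.sin(math.radians(theta)) ** 2
            ):
                # homeostatic polar territories: equatorial divisions stand down
                c.division_time = None
                continue
            if c.founder_class == "M":
                category = "MM"
            else:
                n_mantle_near = sum(
                    1
                    for o in cells
                    if o is not c
                    and o.cls == "M"
                    and math.hypot(o.x - c.x, o.y - c.y) <= 20.0
                )
                category = quota.draw(
                    rng, t, radial_rank, theta, n_mantle_near, config
                )
            truth_categories[(c.lineage, c.node)] = category
            d_classes = {
                "SS": ("S", "S"),
                "HH": ("H", "H"),
                "MM": ("M", "M"),
                "SM": ("S", "M") if rng.uniform() < 0.5 else ("M", "S"),
            }[category]
            dx = rng.normal(0.0, config.daughter_displacement_sd_um)
            dy = rng.normal(0.0, config.daughter_displacement_sd_um)
            dnorm = math.hypot(dx, dy)
            if dnorm > 10.0:  # keep daughters within the lineage sanity gate
                dx *= 10.0 / dnorm
                dy *= 10.0 / dnorm
            gen_d = (2 * c.node).bit_length() - 1
            for k, (sign, cls) in enumerate(zip((1.0, -1.0), d_classes)):
                daughter = _Cell(
                    c.lineage,
                    2 * c.node + k,
                    cls,
                    t + dt,
                    c.x + sign * dx,
                    c.y + sign * dy,
                    None,
                    founder_class=c.founder_class,
                )
                if c.founder_class == "M":
                    # mantle lineages: at most two self-renewing rounds
                    if gen_d < 2 and rng.uniform() < config.m_second_round_probability:
                        tq = _snap(
                            t + dt + max(rng.normal(config.cycle_mean_h, config.cycle_sd_h),
                                         config.cycle_min_h),
                            start,
                            dt,
                        )
                        daughter.division_time = tq if tq <= last_division_frame else None
                elif cls == "S":
                    daughter.division_time = schedule_daughter_division(
                        t + dt, gen_d, n_now + len(newborn), radial_rank
                    )
                newborn.append(daughter)
        cells = [c for c in cells if not (
            c.division_time is not None and abs(c.division_time - t) < dt / 2
        )] + newborn

        # tissue growth (uniform areal expansion toward the new organ
        # radius) plus brownian motion with centripetal containment
        if _frame < n_frames:
            target_radius = r0 * math.sqrt(max(len(cells), 1) / n_founders)
            # cap per-frame expansion so daughters stay near their parent
            factor = min(target_radius / organ_radius, 1.02)
            new_radius = organ_radius * factor
            for c in cells:
                c.x = c.x * factor + rng.normal(0.0, config.random_walk_sd_um)
                c.y = c.y * factor + rng.normal(0.0, config.random_walk_sd_um)
                rr = math.hypot(c.x, c.y)
                if rr > new_radius and rr > 0:
                    c.x *= new_radius / rr
                    c.y *= new_radius / rr
            organ_radius = new_radius
        t = round(t + dt, 9)

    df = pd.DataFrame(
        rows,
        columns=[
            "experiment_id",
            "lineage_id",
            "node_index",
            "time_hpi",
            "x_um",
            "y_um",
            "z_um",
            "cell_class",
        ],
    )
    manifest = ExperimentManifest(
        experiment_id=exp_id,
        frame_interval_h=dt,
        start_hpi=start,
        duration_h=n_frames * dt,
        founder_count=n_founders,
    )
    df = validate_tracks(df, manifest)

    # ground truth recomputable from the table: clone types from leaf classes
    cell_classes: dict[tuple[int, int], str] = {}
    for (lid, node), grp in df.groupby(["lineage_id", "node_index"]):
        cell_classes[(int(lid), int(node))] = str(grp["cell_class"].iloc[-1])
    clone_types: dict[int, str] = {}
    for lid in sorted(df["lineage_id"].unique()):
        nodes = {n for (l, n) in cell_classes if l == lid}
        leaves = {n for n in nodes if 2 * n not in nodes}
        classes = frozenset(cell_classes[(lid, n)] for n in leaves)
        founder_cls = df[(df["lineage_id"] == lid) & (df["node_index"] == 1)][
            "cell_class"
        ].iloc[0]
        if founder_cls == "M":
            ctype = "M" if classes == frozenset("M") else "OTHER"
        else:
            ctype = {
                frozenset("S"): "S",
                frozenset("SM"): "SM",
                frozenset("SH"): "SH",
                frozenset("SHM"): "SHM",
            }.get(classes, "OTHER")
        clone_types[int(lid)] = ctype

    truth = GroundTruth(
        experiment_id=exp_id,
        seed=int(seed),
        clone_types=clone_types,
        division_categories=truth_categories,
        cell_classes=cell_classes,
        config=config,
    )
    return SimulatedExperiment(TrackTable(df, manifest), manifest, truth)


def generate_cohort(config: SimulationConfig) -> list[SimulatedExperiment]:
    """Simulate ``config.n_experiments`` independent recordings.

    Experiment sub-seeds derive deterministically from ``config.seed``.
    """
    ss = np.random.SeedSequence(int(config.seed))
    sub = ss.generate_state(config.n_experiments) % (2**31 - 1)
    return [
        generate_experiment(
            config, int(s), experiment_id=f"s{config.seed}e{i + 1:02d}"
        )
        for i, s in enumerate(sub)
    ]
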