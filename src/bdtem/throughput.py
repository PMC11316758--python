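"""Imaging-rate accounting for beam-deflection TEM acquisition.

Models per-section time as a linear combination of per-event times
(camera exposure, per-tile acquisition overhead, stage step-and-settle,
deflection settle, per-section transition) and derives the standard rate
figures:

* burst rate    — pixels / exposure time only
* montage rate  — pixels / imaging time (stage + deflection included)
* net rate      — pixels / total section time (transition included)
* effective rate — unique (overlap-deduplicated) pixels / total time

plus the imaging duty cycle, sections per day, and days to image a given
tissue volume for a microscope array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .geometry import MontagePlan, ParameterError, montage_unique_pixels

__all__ = [
    "TimingModel",
    "RateReport",
    "burst_rate",
    "section_times",
    "rates_from_times",
    "rate_report",
    "duty_cycle",
    "sections_per_day",
    "days_for_volume",
    "fit_acq_overhead",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display rule)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class TimingModel:
    """Per-event times in seconds."""

    exposure_s: float = 0.120
    acq_overhead_s: float = 0.0  # per-tile software/readout overhead
    stage_move_s: float = 0.037  # mean of 34/40 ms x/y motion times
    stage_settle_s: float = 0.010
    cricket_settle_s: float = 0.006
    transition_s: float = 132.0  # 2.2 min per-section overhead
    uptime_frac: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "exposure_s",
            "acq_overhead_s",
            "stage_move_s",
            "stage_settle_s",
            "cricket_settle_s",
            "transition_s",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0.0 < self.uptime_frac <= 1.0):
            raise ParameterError("uptime_frac must be in (0, 1]")

    def replace(self, **kw) -> "TimingModel":
        return replace(self, **kw)


@dataclass(frozen=True)
class RateReport:
    total_pixels: int
    unique_pixels: int
    imaging_time_s: float
    total_time_s: float
    burst_mpixps: float
    montage_mpixps: float
    net_mpixps: float
    effective_mpixps: float
    duty_cycle_frac: float
    stage_frac: float
    cricket_frac: float
    sections_per_day: int
    days_per_mm3: float

    @property
    def rounded(self) -> dict:
        """Integer-MPix/s display values (half away from zero)."""
        return {
            "burst_mpixps": round_half_away(self.burst_mpixps),
            "montage_mpixps": round_half_away(self.montage_mpixps),
            "net_mpixps": round_half_away(self.net_mpixps),
            "effective_mpixps": round_half_away(self.effective_mpixps),
        }

    def to_dict(self) -> dict:
        d = {
            "total_pixels": self.total_pixels,
            "unique_pixels": self.unique_pixels,
            "imaging_time_s": self.imaging_time_s,
            "total_time_s": self.total_time_s,
            "burst_mpixps": self.burst_mpixps,
            "montage_mpixps": self.montage_mpixps,
            "net_mpixps": self.net_mpixps,
            "effective_mpixps": self.effective_mpixps,
            "duty_cycle_frac": self.duty_cycle_frac,
            "stage_frac": self.stage_frac,
            "cricket_frac": self.cricket_frac,
            "sections_per_day": self.sections_per_day,
            "days_per_mm3": self.days_per_mm3,
        }
        d["display"] = self.rounded
        return d

    def to_table(self) -> str:
        rows = [
            ("imaging time per section", f"{self.imaging_time_s / 60:.1f}", "minute"),
            ("total time per section", f"{self.total_time_s / 60:.1f}", "minute"),
            ("burst imaging rate (imaging only)", f"{round_half_away(self.burst_mpixps)}", "Mpix/s"),
            ("montage imaging rate (w/ stage, Cricket)", f"{round_half_away(self.montage_mpixps)}", "Mpix/s"),
            ("net imaging rate (w/ stage, Cricket, transition)", f"{round_half_away(self.net_mpixps)}", "Mpix/s"),
            ("effective imaging rate (w/ stage, Cricket, transition, overlap)", f"{round_half_away(self.effective_mpixps)}", "Mpix/s"),
            ("imaging duty cycle", f"{self.duty_cycle_frac * 100:.1f}", "%"),
            ("sections per day (1 scope at 24 h)", f"{self.sections_per_day}", "section"),
            ("time to image 1 mm3 (4 scopes at 24/7)", f"{math.ceil(self.days_per_mm3)}", "days"),
        ]
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{name:<{width}}  {val:>8}  {unit}" for name, val, unit in rows)


def burst_rate(tile_pixels: int, exposure_s: float) -> float:
    """Pixels per second counting exposure only, in MPix/s."""
    if exposure_s <= 0:
        raise ParameterError("exposure_s must be positive")
    return tile_pixels / exposure_s / 1e6


def section_times(plan: MontagePlan, timing: TimingModel) -> tuple:
    """Imaging and total time for one section under the linear model.

    imaging = n_tiles*(exposure + acq_overhead)
            + n_supertiles*(stage_move + stage_settle)
            + n_deflections*cricket_settle
    with one stage step per supertile (the first included) and
    ``n_deflections = (tiles_per_supertile - 1) * n_supertiles``.

    Returns ``(imaging_time_s, total_time_s, breakdown)`` where breakdown
    maps each term to its fraction of total time.
    """
    n_t = plan.n_tiles
    n_st = plan.n_supertiles
    n_defl = (plan.spec.tiles_per_supertile - 1) * n_st
    exposure = n_t * timing.exposure_s
    acq = n_t * timing.acq_overhead_s
    stage = n_st * (timing.stage_move_s + timing.stage_settle_s)
    cricket = n_defl * timing.cricket_settle_s
    imaging = exposure + acq + stage + cricket
    total = imaging + timing.transition_s
    breakdown = {
        "exposure": exposure / total,
        "acq_overhead": acq / total,
        "stage": stage / total,
        "cricket": cricket / total,
        "transition": timing.transition_s / total,
    }
    return imaging, total, breakdown


def duty_cycle(plan: MontagePlan, exposure_s: float, total_time_s: float) -> float:
    """Fraction of total section time spent exposing the camera."""
    if exposure_s < 0 or total_time_s <= 0:
        raise ParameterError("times must be positive")
    return plan.n_tiles * exposure_s / total_time_s


def sections_per_day(total_time_s: float) -> int:
    if total_time_s <= 0:
        raise ParameterError("total_time_s must be positive")
    return math.floor(86400.0 / total_time_s)


def days_for_volume(
    depth_mm: float,
    section_thickness_nm: float,
    n_scopes: int,
    total_time_s: float,
    uptime_frac: float = 1.0,
) -> int:
    """Whole days (ceil) for ``n_scopes`` running at ``uptime_frac`` to
    image a volume of the given depth in sections of the given thickness."""
    if section_thickness_nm <= 0 or n_scopes <= 0 or total_time_s <= 0:
        raise ParameterError("arguments must be positive")
    if not (0.0 < uptime_frac <= 1.0):
        raise ParameterError("uptime_frac must be in (0, 1]")
    n_sections = depth_mm * 1e6 / section_thickness_nm
    per_day = n_scopes * (86400.0 / total_time_s) * uptime_frac
    return math.ceil(n_sections / per_day)


def rates_from_times(
    plan: MontagePlan,
    imaging_time_s: float,
    total_time_s: float,
    exposure_s: float | None = None,
    breakdown: dict | None = None,
    section_thickness_nm: float = 45.0,
    n_scopes: int = 4,
    uptime_frac: float = 1.0,
) -> RateReport:
    """Derive the full rate report from a plan and measured/modelled times.

    ``exposure_s`` is needed for the burst rate and duty cycle; it
    defaults to ``imaging_time_s / n_tiles`` (i.e. duty computed as if
    there were no overhead) only when omitted, so pass it explicitly for
    faithful figures.  ``breakdown`` (from :func:`section_times`)
    supplies the stage/deflection fractions; zero when absent.
    """
    if not (0 < imaging_time_s <= total_time_s):
        raise ParameterError("need 0 < imaging_time_s <= total_time_s")
    if exposure_s is None:
        exposure_s = imaging_time_s / plan.n_tiles
    total_px = plan.total_pixels
    unique_px = montage_unique_pixels(plan)
    return RateReport(
        total_pixels=total_px,
        unique_pixels=unique_px,
        imaging_time_s=imaging_time_s,
        total_time_s=total_time_s,
        burst_mpixps=burst_rate(plan.spec.tile_px**2, exposure_s),
        montage_mpixps=total_px / imaging_time_s / 1e6,
        net_mpixps=total_px / total_time_s / 1e6,
        effective_mpixps=unique_px / total_time_s / 1e6,
        duty_cycle_frac=duty_cycle(plan, exposure_s, total_time_s),
        stage_frac=breakdown.get("stage", 0.0) if breakdown else 0.0,
        cricket_frac=breakdown.get("cricket", 0.0) if breakdown else 0.0,
        sections_per_day=sections_per_day(total_time_s),
        days_per_mm3=days_for_volume(
            1.0, section_thickness_nm, n_scopes, total_time_s, uptime_frac
        ),
    )


def rate_report(plan: MontagePlan, timing: TimingModel) -> RateReport:
    """Convenience wrapper: model the times, then derive the rates."""
    imaging, total, breakdown = section_times(plan, timing)
    return rates_from_times(
        plan,
        imaging,
        total,
        exposure_s=timing.exposure_s,
        breakdown=breakdown,
        uptime_frac=timing.uptime_frac,
    )


def fit_acq_overhead(
    plan: MontagePlan, timing_partial: TimingModel, observed_imaging_time_s: float
) -> float:
    """Back-solve the per-tile acquisition overhead from an observed
    imaging time, holding the other per-event times fixed.

    ``section_times`` with the fitted value reproduces the observed
    imaging time to numerical precision.
    """
    base = timing_partial.replace(acq_overhead_s=0.0)
    imaging0, _, _ = section_times(plan, base)
    if observed_imaging_time_s < plan.n_tiles * timing_partial.exposure_s:
        raise ParameterError(
            "observed imaging time is shorter than exposure-only time"
        )
    return (observed_imaging_time_s - imaging0) / plan.n_tiles
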