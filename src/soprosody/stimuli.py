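"""Assembly of manipulated audio-stimulus specifications.

Each stimulus is an "event" clause (left untouched) followed by the
connective *so*, whose prosody is imposed: the connective's f0 contour is
projected onto a fitted FPCA model, its 2nd/3rd component weights are
replaced by the condition's targets, the contour is re-solved every 5 ms
at the condition's target duration (285 ms subjective / 235 ms objective),
segment durations are rescaled preserving their original ratio, and the
silent gap between clause and connective is removed.  The builder emits
restyling *specifications* (PitchTier + TextGrid files) for an external
PSOLA resynthesizer rather than waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import praat_io
from .contours import Contour, FPCAModel, normalize_time, project, reconstruct, restyle_scores
from .errors import DegenerateTokenError
from .specs import ProsodySpec, default_spec

__all__ = ["SegmentedToken", "StimulusRecord", "scale_duration", "remove_gap",
           "build_stimulus", "build_stimulus_set", "export_praat"]


@dataclass(frozen=True)
class SegmentedToken:
    """A token with ordered phone segments and an f0 contour spanning it.

    The connective *so* is, by default, the two segments /s/ and /oʊ/.
    """

    segments: tuple[tuple[str, float], ...]   # (phone label, duration ms)
    contour: Contour

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(
            (str(lab), float(dur)) for lab, dur in self.segments))
        if any(dur <= 0 for _, dur in self.segments):
            raise DegenerateTokenError("segment durations must be positive")
        if abs(self.contour.duration_ms - self.total_duration_ms) > 1.0:
            raise ValueError(
                "contour extent must equal the summed segment durations (±1 ms)")

    @property
    def total_duration_ms(self) -> float:
        return float(sum(dur for _, dur in self.segments))


@dataclass(frozen=True)
class StimulusRecord:
    """One manipulated clip: untouched clause contour + manipulated connective."""

    clip_id: str
    pair_id: int                      # 1..15
    condition: str
    event_clause_contour: Contour
    connective: SegmentedToken
    gap_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.gap_ms < 0:
            raise ValueError("gap_ms must be >= 0")

    @property
    def total_duration_ms(self) -> float:
        return (self.event_clause_contour.duration_ms + self.gap_ms
                + self.connective.total_duration_ms)


def scale_duration(token: SegmentedToken, target_total_ms: float) -> SegmentedToken:
    """Rescale every segment (and the contour's time axis) by the same
    factor so the token totals ``target_total_ms``; segment ratios are
    preserved exactly."""
    if target_total_ms <= 0:
        raise ValueError("target_total_ms must be positive")
    current = token.total_duration_ms
    if current <= 0:
        raise DegenerateTokenError("token has zero total duration")
    factor = target_total_ms / current
    segments = tuple((lab, dur * factor) for lab, dur in token.segments)
    t0 = token.contour.times[0]
    contour = replace(token.contour, times=t0 + (token.contour.times - t0) * factor)
    return SegmentedToken(segments=segments, contour=contour)


def remove_gap(record: StimulusRecord) -> StimulusRecord:
    """Remove the silent interval between clause and connective by shifting
    the connective earlier; both contours are internally unchanged."""
    if record.gap_ms == 0:
        return record
    shifted = SegmentedToken(
        segments=record.connective.segments,
        contour=record.connective.contour.shifted(-record.gap_ms),
    )
    return replace(record, gap_ms=0.0, connective=shifted)


def build_stimulus(
    clip: StimulusRecord,
    model: FPCAModel,
    spec: ProsodySpec,
    grid_size: int = 101,
    step_ms: float = 5.0,
) -> StimulusRecord:
    """Apply the full connective manipulation to one clip.

    The connective contour is replaced by the restyled reconstruction at
    the condition's target duration, segment durations are rescaled
    ratio-preservingly, and the clause/connective gap is removed.  The
    event-clause contour is passed through bit-identically.
    """
    conn = clip.connective
    scores = project(model, normalize_time(conn.contour, grid_size))
    styled = restyle_scores(scores, spec.condition, spec)
    onset = float(conn.contour.times[0])
    new_contour = reconstruct(model, styled, spec.target_duration_ms, step_ms)
    scaled = scale_duration(conn, spec.target_duration_ms)
    new_conn = SegmentedToken(
        segments=scaled.segments,
        contour=new_contour.shifted(onset),
    )
    built = replace(clip, condition=spec.condition, connective=new_conn,
                    clip_id=f"{clip.clip_id}_{spec.condition[0].upper()}")
    return remove_gap(built)


def build_stimulus_set(
    clips: list[StimulusRecord],
    model: FPCAModel,
    specs: tuple[ProsodySpec, ...] = (),
    **kwargs,
) -> list[StimulusRecord]:
    """Build every clip in both prosodic conditions (15 pairs -> 30 stimuli)."""
    if not specs:
        specs = (default_spec("subjective"), default_spec("objective"))
    return [build_stimulus(clip, model, spec, **kwargs)
            for clip in clips for spec in specs]


def export_praat(record: StimulusRecord, directory: str | Path) -> dict[str, Path]:
    """Write the record's restyling specification as PitchTier + TextGrid.

    The PitchTier holds the manipulated connective contour; the TextGrid
    has a clause/connective tier and a segment tier.  Durations are
    rounded half-up to 0.1 ms only at this boundary.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = record.clip_id
    pt_path = directory / f"{stem}.PitchTier"
    tg_path = directory / f"{stem}.TextGrid"
    praat_io.write_pitch_tier(record.connective.contour, pt_path)

    def r(x: float) -> float:
        return float(np.floor(x * 10 + 0.5) / 10)  # half-up to 0.1 ms

    clause_end = record.event_clause_contour.times[-1]
    conn_start = float(record.connective.contour.times[0])
    tiers: dict[str, list[tuple[float, float, str]]] = {
        "clause": [
            (r(record.event_clause_contour.times[0]), r(clause_end), "event"),
            (r(conn_start), r(conn_start + record.connective.total_duration_ms),
             "connective"),
        ],
        "segments": [],
    }
    t = conn_start
    for lab, dur in record.connective.segments:
        tiers["segments"].append((r(t), r(t + dur), lab))
        t += dur
    praat_io.write_textgrid(tiers, tg_path)
    return {"pitch_tier": pt_path, "textgrid": tg_path}
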