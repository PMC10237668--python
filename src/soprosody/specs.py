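"""Per-condition prosodic targets for the connective *so*.

The production study behind the stimuli estimated that, relative to
objective (CAUSE-CONSEQUENCE) causality, the connective *so* in subjective
(CLAIM-ARGUMENT) causality is about 50 ms longer and carries an f0 contour
that is more concave with a lower onset.  Expressed in the FPCA
decomposition of the contour set, the condition-typical component weights
and durations are:

==========  ==========  =========  =========
condition   duration    s2 target  s3 target
==========  ==========  =========  =========
subjective  285 ms      +0.335     -0.065
objective   235 ms      -0.515     +0.025
==========  ==========  =========  =========

``ProsodySpec`` bundles these targets; ``default_spec`` returns the
condition's canonical values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConditionError

SUBJECTIVE = "subjective"
OBJECTIVE = "objective"
CONDITIONS = (SUBJECTIVE, OBJECTIVE)


@dataclass(frozen=True)
class ProsodySpec:
    """Target duration and FPC-weight substitutions for one condition.

    Parameters
    ----------
    condition
        ``"subjective"`` or ``"objective"``.
    target_duration_ms
        Total duration the manipulated connective must have.
    s2_target, s3_target
        Replacement weights for the second and third principal-component
        contours; the first weight (overall level/tilt) is never touched,
        so token identity is preserved.
    """

    condition: str
    target_duration_ms: float
    s2_target: float
    s3_target: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConditionError(f"unknown condition {self.condition!r}")
        if not self.target_duration_ms > 0:
            raise ValueError("target_duration_ms must be positive")


SUBJECTIVE_SPEC = ProsodySpec(SUBJECTIVE, 285.0, +0.335, -0.065)
OBJECTIVE_SPEC = ProsodySpec(OBJECTIVE, 235.0, -0.515, +0.025)


def default_spec(condition: str) -> ProsodySpec:
    """Return the canonical :class:`ProsodySpec` for *condition*."""
    if condition == SUBJECTIVE:
        return SUBJECTIVE_SPEC
    if condition == OBJECTIVE:
        return OBJECTIVE_SPEC
    raise ConditionError(f"unknown condition {condition!r}")
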