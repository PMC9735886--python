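"""Sleep-stage label conventions (AASM five-class scheme)."""

from __future__ import annotations

# Canonical class order used for all label arrays, probability vectors and
# confusion matrices: W < N1 < N2 < N3 < REM.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
N_STAGES: int = len(STAGES)

STAGE_TO_INDEX: dict[str, int] = {name: i for i, name in enumerate(STAGES)}

# Conventional hypnogram display order (top to bottom): wake on top, REM just
# below it, then light to deep non-REM.
HYPNOGRAM_ORDER: tuple[str, ...] = ("W", "REM", "N1", "N2", "N3")


def stage_name(index: int) -> str:
    """Map a class index to its stage name."""
    return STAGES[index]
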