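"""Small shared numerics."""

from __future__ import annotations

from .errors import FluxError


def percent_decline(initial: float, final: float) -> float:
    """Percentage decline from ``initial`` to ``final``: 100 * (1 - final/initial).

    National SO2 emission statistics are typically reported as whole
    percentages; callers wanting the printed-style figure should floor
    the result.
    """
    if initial <= 0:
        raise FluxError(f"initial must be > 0, got {initial}")
    if final < 0:
        raise FluxError(f"final must be >= 0, got {final}")
    return 100.0 * (1.0 - final / initial)
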