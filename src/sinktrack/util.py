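"""Small shared numerics."""

from __future__ import annotations

__all__ = ["relative_increase"]


def relative_increase(baseline: float, value: float) -> float:
    """Relative change from ``baseline`` to ``value``, in percent.

    Used e.g. to express the gain in species-level taxonomic classification
    rate of full-length 16S sequences over short reads:
    ``relative_increase(56.8, 74.0)`` is about 30.3 (percent).
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return (value - baseline) / baseline * 100.0
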