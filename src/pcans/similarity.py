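"""Three-attribute peak similarity score.

Two peaks are compared on height ``h``, width-at-half-height ``w`` and
chemical shift ``c``.  Height and width similarities are the relative
difference scaled by the larger value, subtracted from one; chemical-shift
similarity is the difference scaled by the maximum acceptable movement ``m``,
subtracted from one:

    score = p_h * (1 - |h_a - h_b| / max(h_a, h_b))
          + p_w * (1 - |w_a - w_b| / max(w_a, w_b))
          + p_c * (1 - |c_a - c_b| / m)

The height and width terms lie in (0, 1]; the shift term goes negative once
the peaks are further apart than ``m`` (enforcement of the window happens in
the alignment layer, which substitutes the boundary penalty there).
"""

from __future__ import annotations

from .types import AlignmentParams, Peak

__all__ = ["score", "attribute_similarities"]


def attribute_similarities(
    a: Peak, b: Peak, params: AlignmentParams
) -> tuple[float, float, float]:
    """The three unweighted similarity terms ``(s_h, s_w, s_c)``.

    Used directly by the naive aligner, which requires *each* term to reach
    its threshold rather than the weighted sum.
    """
    if not (a.height > 0 and b.height > 0):
        raise ValueError("peak heights must be > 0")
    if not (a.width > 0 and b.width > 0):
        raise ValueError("peak widths must be > 0")
    s_h = 1.0 - abs(a.height - b.height) / max(a.height, b.height)
    s_w = 1.0 - abs(a.width - b.width) / max(a.width, b.width)
    s_c = 1.0 - abs(a.position - b.position) / params.m
    return (s_h, s_w, s_c)


def score(a: Peak, b: Peak, params: AlignmentParams) -> float:
    """Weighted similarity between two peaks; 1.0 iff identical attributes
    (with strictly positive weights), symmetric in its arguments."""
    s_h, s_w, s_c = attribute_similarities(a, b, params)
    return params.p_h * s_h + params.p_w * s_w + params.p_c * s_c
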