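"""Canonical region list and the asymmetry-index closed form.

Thirteen left/right homologous AAL regions contiguous or functionally
associated with mesial temporal structures are used as features.  The
asymmetry index (AI) of a region pair is

    AI = 200 * (L - R) / (L + R)

where L and R are the mean uptake (counts) over the left and right
member of the pair.  Positive AI means higher uptake on the left, so
ipsilateral hypometabolism in left TLE yields negative temporal AIs.
"""

from __future__ import annotations

#: Feature (pair) names in canonical column order.
REGION_NAMES: tuple[str, ...] = (
    "Opercular part of inferior frontal gyrus",
    "Rolandic operculum",
    "Insula",
    "Hippocampus",
    "Parahippocampal gyrus",
    "Amygdala",
    "Supramarginal gyrus",
    "Thalamus",
    "Superior temporal gyrus",
    "Temporal pole of superior temporal gyrus",
    "Middle temporal gyrus",
    "Temporal pole of middle temporal gyrus",
    "Inferior temporal gyrus",
)

#: The two lateralization classes, in sorted order.
CLASSES: tuple[str, str] = ("Left", "Right")


def expected_ai(delta: float, contralateral_gain: float = 0.0,
                side: str = "Left") -> float:
    """Closed-form AI for a fractional ipsilateral uptake reduction.

    With ipsilateral uptake ``B*(1 - delta)`` and contralateral uptake
    ``B*(1 + contralateral_gain)``, the common baseline ``B`` cancels:

        Left TLE:  AI = 200 * ((1-d) - (1+g)) / ((1-d) + (1+g))
        Right TLE: the same magnitude with opposite sign.

    For ``g = 0`` this is ``-200*d/(2-d)`` on the left,
    e.g. delta=0.06 -> -6.1856 for a left-TLE subject.
    """
    lo = 1.0 - delta
    hi = 1.0 + contralateral_gain
    if side == "Left":
        left, right = lo, hi
    elif side == "Right":
        left, right = hi, lo
    else:
        raise ValueError(f"side must be 'Left' or 'Right', got {side!r}")
    return 200.0 * (left - right) / (left + right)
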