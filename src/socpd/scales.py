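"""Clinical rating-scale registry.

Each scale carries its published score range, the healthy-control
generating distribution used by the synthetic cohort, and whether a
higher score means better performance (cognitive tests) or worse
symptoms (everything else).
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class ScaleInfo:
    name: str
    lo: float
    hi: float
    hc_mean: float
    hc_sd: float
    higher_is_better: bool = False


# Healthy-control means/SDs approximate normative values for elderly
# controls; ranges are the published scale bounds.
SCALES: dict[str, ScaleInfo] = {
    s.name: s
    for s in [
        ScaleInfo("rbdsq", 0, 13, 2.0, 2.0),
        ScaleInfo("scopa_aut", 0, 69, 6.0, 3.0),
        ScaleInfo("updrs1", 0, 52, 2.0, 1.8),
        ScaleInfo("updrs2", 0, 52, 1.0, 1.5),
        ScaleInfo("updrs3", 0, 132, 2.0, 2.5),
        ScaleInfo("updrs4", 0, 24, 0.0, 0.5),
        ScaleInfo("moca", 0, 30, 27.5, 1.8, higher_is_better=True),
        ScaleInfo("sdmt", 0, 110, 47.0, 10.0, higher_is_better=True),
        ScaleInfo("hvlt_recall", 0, 12, 9.0, 2.2, higher_is_better=True),
        ScaleInfo("lns", 0, 21, 10.5, 2.5, higher_is_better=True),
        ScaleInfo("semantic_fluency", 0, 100, 48.0, 11.0, higher_is_better=True),
        ScaleInfo("benton", 0, 15, 13.0, 1.8, higher_is_better=True),
        ScaleInfo("gds", 0, 15, 5.0, 1.5),
        ScaleInfo("stai", 20, 80, 47.0, 10.0),
    ]
}

#: Neuropsychological tests entering the mild-cognitive-impairment rule.
COGNITIVE_TESTS = (
    "moca",
    "sdmt",
    "hvlt_recall",
    "lns",
    "semantic_fluency",
    "benton",
)

#: Scales defining body-first status against the healthy-control reference.
SOC_SCALES = ("rbdsq", "scopa_aut")


def clip_round(x, scale: ScaleInfo):
    """Round to integer scale points and clip to the published range."""
    import numpy as np

    return np.clip(np.round(x), scale.lo, scale.hi)
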