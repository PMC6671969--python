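"""Brain-parameter catalogues.

A screen measures a fixed panel of morphometric parameters (areas, lengths,
one folia count) on stereotaxically defined histological sections.  Each
parameter belongs to one of six anatomical categories and one of four
"critical sections" (three coronal Bregma positions plus one sagittal
Lateral position).  The catalogue carries the wild-type mean and
coefficient of variation used by the synthetic generator and the
category/section lookup used when rolling association results up to
gene-level calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = (
    "brain_size",
    "commissures",
    "ventricles",
    "cortex",
    "subcortex",
    "cerebellum_pons",
)

SECTIONS = ("B+0.98", "B-1.34", "B-5.80", "L0.60")

#: The two coronal sections on which phenotypic similarity is aggregated.
CORONAL_SIMILARITY_SECTIONS = ("B+0.98", "B-1.34")

MEASURES = ("area", "length", "count")

#: Conventional identifier of the whole-brain area parameter used for
#: normalised structural correlations.
TOTAL_BRAIN_AREA = "total_brain_area"


@dataclass(frozen=True)
class ParameterDef:
    """One morphometric parameter of the screen's panel."""

    parameter_id: str
    category: str
    section: str
    measure: str
    wt_mean: float
    wt_cv: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.section not in SECTIONS:
            raise ValueError(f"unknown section {self.section!r}")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if not self.wt_mean > 0:
            raise ValueError(f"wt_mean must be positive, got {self.wt_mean}")
        if not 0 < self.wt_cv < 1:
            raise ValueError(f"wt_cv must be in (0, 1), got {self.wt_cv}")


def catalogue_frame(params: list[ParameterDef]) -> pd.DataFrame:
    """Return the catalogue as a DataFrame indexed by parameter_id."""
    ids = [p.parameter_id for p in params]
    if len(set(ids)) != len(ids):
        raise ValueError("parameter_id values must be unique within a catalogue")
    return pd.DataFrame(
        {
            "parameter_id": ids,
            "category": [p.category for p in params],
            "section": [p.section for p in params],
            "measure": [p.measure for p in params],
            "wt_mean": [p.wt_mean for p in params],
            "wt_cv": [p.wt_cv for p in params],
        }
    ).set_index("parameter_id", drop=False)


def make_catalogue(
    n_per_section: dict[str, int],
    wt_cv: float = 0.05,
    seed: int = 0,
) -> list[ParameterDef]:
    """Build a synthetic catalogue with ``n_per_section[section]`` parameters.

    Categories and measures are assigned cyclically; wild-type means are
    drawn log-uniformly over two decades (0.1–10 mm² or mm) so parameters
    span realistic scale differences between, say, a commissure width and
    the total brain area.  The first parameter of the first coronal section
    is always the whole-brain area (category ``brain_size``), so normalised
    structural correlations are well defined on any catalogue.
    """
    rng = np.random.default_rng(seed)
    params: list[ParameterDef] = []
    cat_cycle = 0
    for section in SECTIONS:
        n = n_per_section.get(section, 0)
        for i in range(n):
            if section == "B+0.98" and i == 0:
                params.append(
                    ParameterDef(
                        TOTAL_BRAIN_AREA, "brain_size", section, "area",
                        wt_mean=50.0, wt_cv=wt_cv,
                    )
                )
                continue
            category = CATEGORIES[cat_cycle % len(CATEGORIES)]
            cat_cycle += 1
            measure = "length" if category == "commissures" else "area"
            pid = f"{section}:{category}_{i:02d}"
            wt_mean = float(10 ** rng.uniform(-1, 1))
            params.append(
                ParameterDef(pid, category, section, measure, wt_mean, wt_cv)
            )
    return params


def default_catalogue(wt_cv: float = 0.05, seed: int = 0) -> list[ParameterDef]:
    """The default 118-parameter panel.

    39 parameters on each of the two analysed coronal sections, 10 on the
    caudal coronal section and 30 on the sagittal section — 118 in total,
    covering all six anatomical categories.
    """
    return make_catalogue(
        {"B+0.98": 39, "B-1.34": 39, "B-5.80": 10, "L0.60": 30},
        wt_cv=wt_cv,
        seed=seed,
    )
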