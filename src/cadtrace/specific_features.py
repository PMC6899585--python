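"""Transgenic-specific feature subtraction.

A feature is "specific" to the transgenic (case) lines when it is detected
in enough replicates of at least one case genotype while remaining
essentially undetected in the control — a reproducible, replicate-presence
proxy for the study workflow of subtracting control peaks and then manually
removing alignment artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .feature_core import FeatureID, FeatureMatrix


class SpecificityError(ValueError):
    pass


@dataclass(frozen=True)
class SpecificityParams:
    """``min_case_replicates=None`` means "all replicates of one case line"."""

    min_case_replicates: int | None = None
    max_control_detections: int = 0

    def __post_init__(self) -> None:
        if self.min_case_replicates is not None and self.min_case_replicates < 1:
            raise SpecificityError("min_case_replicates must be >= 1")
        if self.max_control_detections < 0:
            raise SpecificityError("max_control_detections must be >= 0")


def find_specific(matrix: FeatureMatrix, case_genotypes: list[str],
                  control_genotype: str,
                  params: SpecificityParams = SpecificityParams()
                  ) -> list[FeatureID]:
    """Features detected in >= r replicates of any case line and in at most
    ``max_control_detections`` control samples.

    Case lines combine by "any line qualifies" — the lines are pooled as one
    class, so reproducible presence in a single line suffices.
    """
    genotypes = set(matrix.genotypes())
    for g in list(case_genotypes) + [control_genotype]:
        if g not in genotypes:
            raise SpecificityError(f"genotype {g!r} not present in matrix")
    mask = matrix.detection_mask()
    case_columns = {g: [j for j, s in enumerate(matrix.samples) if s.genotype == g]
                    for g in case_genotypes}
    control_columns = [j for j, s in enumerate(matrix.samples)
                       if s.genotype == control_genotype]
    out = []
    for i, feature in enumerate(matrix.features):
        control_hits = int(mask[i, control_columns].sum())
        if control_hits > params.max_control_detections:
            continue
        for g, cols in case_columns.items():
            required = params.min_case_replicates or len(cols)
            if int(mask[i, cols].sum()) >= required:
                out.append(feature)
                break
    return out


def specificity_table(matrix: FeatureMatrix, features: list[FeatureID],
                      genotypes: list[str] | None = None) -> pd.DataFrame:
    """Per-genotype detection counts for the selected features."""
    genotypes = genotypes or matrix.genotypes()
    mask = matrix.detection_mask()
    columns = {g: [j for j, s in enumerate(matrix.samples) if s.genotype == g]
               for g in genotypes}
    rows = []
    for f in features:
        i = matrix.feature_index(f)
        row: dict[str, object] = {"feature_id": f.render()}
        for g, cols in columns.items():
            row[f"detected_{g}"] = int(mask[i, cols].sum())
            row[f"n_{g}"] = len(cols)
        rows.append(row)
    return pd.DataFrame(rows)
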