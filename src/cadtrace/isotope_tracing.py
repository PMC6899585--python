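"""15N isotopologue pair detection, %EF computation and labeling classification.

A labeled metabolite appears as a feature pair: the monoisotopic peak M and a
heavy peak M+1 shifted by the 15N-14N mass difference (0.9970 Da) at the same
retention time.  The percentage isotope enrichment factor

    %EF = 100 * I(M+1) / (I(M) + I(M+1))

is computed per replicate and treatment, then corrected for the
natural-abundance baseline measured in non-labeled-fed (NL) samples.  The
dual-isotopomer design ([alpha-15N]- vs [epsilon-15N]-lysine, AL vs EL) then
classifies each metabolite's nitrogen provenance: equal AL/EL labeling at the
level of the cadaverine reference means both nitrogens come from cadaverine;
equal labeling at half that level means one nitrogen was retained through the
symmetric cadaverine intermediate; labeling under only one treatment means
regiospecific derivation from the corresponding lysine nitrogen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_core import FeatureID, FeatureMatrix
from .synthetic_data import DELTA_15N


class TracingError(ValueError):
    pass


# -- pair search -----------------------------------------------------------


@dataclass(frozen=True)
class PairSearchParams:
    """Mass-shift pair search: one heavy atom, 5 ppm, 0.1 min by default."""

    delta_mass: float = DELTA_15N
    ppm_tolerance: float = 5.0
    rt_tolerance: float = 0.1
    max_heavy: int = 1

    def __post_init__(self) -> None:
        if min(self.delta_mass, self.ppm_tolerance, self.rt_tolerance) <= 0:
            raise TracingError("pair-search parameters must be > 0")
        if self.max_heavy != 1:
            raise TracingError("only the M+1 channel is searched (max_heavy=1)")


@dataclass(frozen=True)
class IsotopologPair:
    light: FeatureID
    heavy: FeatureID
    observed_shift: float
    ppm_error: float      # vs delta_mass, relative to the expected heavy m/z
    rt_difference: float

    def __post_init__(self) -> None:
        if self.heavy.mz <= self.light.mz:
            raise TracingError("heavy m/z must exceed light m/z")
        if self.heavy.mode != self.light.mode:
            raise TracingError("pair members must share a chromatography mode")


def find_isotopolog_pairs(matrix: FeatureMatrix,
                          params: PairSearchParams = PairSearchParams()
                          ) -> list[IsotopologPair]:
    """For each light feature, the best M+1 candidate within tolerance.

    A candidate must sit at the expected m/z (light + delta) within the ppm
    tolerance — ppm computed on the expected heavy m/z — and within the RT
    tolerance.  Ties break by smallest ppm error, then smallest RT
    difference, then m/z.  Equivalent to a brute-force all-pairs scan.
    """
    by_mode: dict[str, list[FeatureID]] = {}
    for f in matrix.features:
        by_mode.setdefault(f.mode, []).append(f)
    pairs: list[IsotopologPair] = []
    for mode in sorted(by_mode):
        feats = sorted(by_mode[mode], key=lambda f: (f.mz, f.rt))
        mzs = np.array([f.mz for f in feats])
        for light in by_mode[mode]:
            expected = light.mz + params.delta_mass
            window = expected * params.ppm_tolerance * 1e-6
            lo = int(np.searchsorted(mzs, expected - window, side="left"))
            hi = int(np.searchsorted(mzs, expected + window, side="right"))
            best: tuple[float, float, float, FeatureID] | None = None
            for cand in feats[lo:hi]:
                if cand == light:
                    continue
                ppm = abs(cand.mz - expected) / expected * 1e6
                drt = abs(cand.rt - light.rt)
                if ppm >= params.ppm_tolerance or drt > params.rt_tolerance:
                    continue
                key = (ppm, drt, cand.mz, cand)
                if best is None or key[:3] < best[:3]:
                    best = key
            if best is not None:
                cand = best[3]
                pairs.append(IsotopologPair(light, cand, cand.mz - light.mz,
                                            (cand.mz - expected) / expected * 1e6,
                                            cand.rt - light.rt))
    pairs.sort(key=lambda p: (p.light.mode, p.light.mz, p.light.rt))
    return pairs


# -- enrichment factors ----------------------------------------------------


def compute_ef(i_m: float, i_m1: float) -> float:
    """Raw %EF = 100 * I(M+1) / (I(M) + I(M+1))."""
    if i_m < 0 or i_m1 < 0:
        raise TracingError("intensities must be >= 0")
    total = i_m + i_m1
    if total == 0:
        raise TracingError("%EF undefined: both isotopologue intensities are 0")
    return 100.0 * i_m1 / total


def correct_ef(ef_treated: float, ef_baseline: float,
               method: str = "normalize") -> tuple[float, bool]:
    """Correct a treated %EF for the natural-abundance NL baseline.

    ``normalize`` (default) is the excess-enrichment normalization
    100*(EF_t - EF_NL)/(100 - EF_NL); ``subtract`` is the plain difference.
    Both floor at 0; returns (corrected, below_baseline_flag).
    """
    if not (0 <= ef_treated <= 100 and 0 <= ef_baseline < 100):
        raise TracingError("%EF values must lie in [0, 100], baseline < 100")
    below = ef_treated < ef_baseline
    if method == "normalize":
        corrected = 100.0 * (ef_treated - ef_baseline) / (100.0 - ef_baseline)
    elif method == "subtract":
        corrected = ef_treated - ef_baseline
    else:
        raise TracingError(f"unknown correction method {method!r}")
    return max(corrected, 0.0), below


@dataclass
class EnrichmentRecord:
    """Per-pair, per-treatment intensities and enrichment factors."""

    pair: IsotopologPair
    treatment: str
    mean_i_m: float
    mean_i_m1: float
    replicate_efs: list[float]
    raw_ef: float
    corrected_ef: float | None = None
    flags: list[str] = field(default_factory=list)


def enrichment_records(matrix: FeatureMatrix, pairs: list[IsotopologPair],
                       treatments: tuple[str, ...] = ("AL", "EL", "NL"),
                       correction: str = "normalize") -> list[EnrichmentRecord]:
    """Compute raw and NL-corrected %EF for every pair and treatment.

    Per-replicate %EF values are averaged arithmetically; the NL record's raw
    %EF serves as the correction baseline for AL and EL.
    """
    records: list[EnrichmentRecord] = []
    for pair in pairs:
        i_light = matrix.feature_index(pair.light)
        i_heavy = matrix.feature_index(pair.heavy)
        per_treatment: dict[str, EnrichmentRecord] = {}
        for treatment in treatments:
            cols = [j for j, s in enumerate(matrix.samples) if s.treatment == treatment]
            if not cols:
                continue
            i_m = matrix.intensities[i_light, cols]
            i_m1 = matrix.intensities[i_heavy, cols]
            efs, flags = [], []
            for m, m1 in zip(i_m, i_m1):
                if m + m1 == 0:
                    flags.append("replicate with both isotopologues undetected")
                    continue
                efs.append(compute_ef(m, m1))
            if not efs:
                rec = EnrichmentRecord(pair, treatment, float(i_m.mean()),
                                       float(i_m1.mean()), [], math.nan,
                                       flags=flags + ["undefined %EF"])
            else:
                rec = EnrichmentRecord(pair, treatment, float(i_m.mean()),
                                       float(i_m1.mean()), efs,
                                       float(np.mean(efs)), flags=flags)
            per_treatment[treatment] = rec
        baseline = per_treatment.get("NL")
        baseline_ef = baseline.raw_ef if baseline is not None else 0.0
        if baseline is not None and not math.isnan(baseline.raw_ef):
            baseline.corrected_ef = 0.0
        for treatment in ("AL", "EL"):
            rec = per_treatment.get(treatment)
            if rec is None or math.isnan(rec.raw_ef):
                continue
            base = 0.0 if (baseline is None or math.isnan(baseline_ef)) else baseline_ef
            corrected, below = correct_ef(rec.raw_ef, base, correction)
            rec.corrected_ef = corrected
            if below:
                rec.flags.append("below NL baseline")
        records.extend(per_treatment[t] for t in treatments if t in per_treatment)
    return records


# -- classification --------------------------------------------------------


LABELING_CLASSES = ("both_nitrogens", "one_nitrogen_via_symmetric_intermediate",
                    "regiospecific_alpha", "regiospecific_epsilon", "unlabeled",
                    "ambiguous")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Operational bins for the qualitative dual-isotopomer readout.

    A metabolite counts as labeled above ``min_enrichment_pct`` corrected %EF;
    AL/EL agreement requires relative asymmetry |AL-EL|/mean below
    ``asymmetry_tolerance``; the ratio to the cadaverine reference falls in
    ``full_band`` for both-nitrogen metabolites and ``half_band`` for
    one-nitrogen metabolites routed through the symmetric intermediate.
    """

    min_enrichment_pct: float = 5.0
    asymmetry_tolerance: float = 0.5
    full_band: tuple[float, float] = (0.75, 1.25)
    half_band: tuple[float, float] = (0.35, 0.65)


@dataclass(frozen=True)
class LabelClassification:
    feature: FeatureID
    label_class: str
    rho: float | None          # ratio to the cadaverine reference %EF
    asymmetry: float | None    # |EF_AL - EF_EL| / mean
    reason: str = ""


def classify_labeling(record_al: EnrichmentRecord | None,
                      record_el: EnrichmentRecord | None,
                      reference_al: EnrichmentRecord,
                      reference_el: EnrichmentRecord,
                      thresholds: ClassificationThresholds = ClassificationThresholds()
                      ) -> LabelClassification:
    """Classify one metabolite's nitrogen provenance from its AL/EL %EF."""
    ref_efs = [reference_al.corrected_ef, reference_el.corrected_ef]
    if any(e is None or e <= thresholds.min_enrichment_pct for e in ref_efs):
        raise TracingError("cadaverine reference must be enriched above the "
                           "minimum threshold in both treatments")
    feature = (record_al or record_el).pair.light if (record_al or record_el) else None
    if record_al is None or record_el is None or \
            record_al.corrected_ef is None or record_el.corrected_ef is None:
        if feature is None:
            raise TracingError("no enrichment records supplied")
        return LabelClassification(feature, "ambiguous", None, None,
                                   "missing treatment data")
    ef_al, ef_el = record_al.corrected_ef, record_el.corrected_ef
    labeled_al = ef_al > thresholds.min_enrichment_pct
    labeled_el = ef_el > thresholds.min_enrichment_pct
    if not labeled_al and not labeled_el:
        return LabelClassification(feature, "unlabeled", None, None,
                                   "below minimum enrichment in both treatments")
    if labeled_al != labeled_el:
        cls = "regiospecific_alpha" if labeled_al else "regiospecific_epsilon"
        return LabelClassification(feature, cls, None, None,
                                   "labeled under exactly one treatment")
    mean_ef = (ef_al + ef_el) / 2.0
    asymmetry = abs(ef_al - ef_el) / mean_ef
    if asymmetry > thresholds.asymmetry_tolerance:
        return LabelClassification(feature, "ambiguous", None, asymmetry,
                                   "AL/EL asymmetry exceeds tolerance")
    ref_mean = (ref_efs[0] + ref_efs[1]) / 2.0
    rho = mean_ef / ref_mean
    lo_f, hi_f = thresholds.full_band
    lo_h, hi_h = thresholds.half_band
    if lo_f <= rho <= hi_f:
        cls, reason = "both_nitrogens", "labeled at the cadaverine level"
    elif lo_h <= rho <= hi_h:
        cls, reason = ("one_nitrogen_via_symmetric_intermediate",
                       "labeled at half the cadaverine level")
    else:
        cls, reason = "ambiguous", "ratio outside both bands"
    return LabelClassification(feature, cls, rho, asymmetry, reason)


def classify_all(records: list[EnrichmentRecord],
                 reference_light: FeatureID,
                 thresholds: ClassificationThresholds = ClassificationThresholds()
                 ) -> list[LabelClassification]:
    """Classify every paired feature against the given reference feature."""
    by_feature: dict[FeatureID, dict[str, EnrichmentRecord]] = {}
    for rec in records:
        by_feature.setdefault(rec.pair.light, {})[rec.treatment] = rec
    if reference_light not in by_feature:
        raise TracingError(f"reference feature {reference_light.render()} has no "
                           "enrichment records")
    ref = by_feature[reference_light]
    if "AL" not in ref or "EL" not in ref:
        raise TracingError("reference feature lacks AL or EL records")
    out = []
    for feature in sorted(by_feature, key=lambda f: (f.mode, f.mz, f.rt)):
        if feature == reference_light:
            continue
        recs = by_feature[feature]
        out.append(classify_labeling(recs.get("AL"), recs.get("EL"),
                                     ref["AL"], ref["EL"], thresholds))
    return out


def find_reference_pair(pairs: list[IsotopologPair], mz: float,
                        ppm_tolerance: float = 10.0) -> IsotopologPair:
    """Locate the reference (cadaverine) pair by its light-feature m/z."""
    candidates = [p for p in pairs
                  if abs(p.light.mz - mz) / mz * 1e6 < ppm_tolerance]
    if not candidates:
        raise TracingError(f"no pair with light m/z within {ppm_tolerance} ppm of {mz}")
    return min(candidates, key=lambda p: abs(p.light.mz - mz))


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_id": r.pair.light.render(),
        "heavy_feature_id": r.pair.heavy.render(),
        "mode": r.pair.light.mode,
        "treatment": r.treatment,
        "mean_I_M": r.mean_i_m,
        "mean_I_M1": r.mean_i_m1,
        "raw_EF_pct": r.raw_ef,
        "corrected_EF_pct": r.corrected_ef,
        "flags": ";".join(r.flags),
    } for r in records])


def classification_table(classifications: list[LabelClassification]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_id": c.feature.render(),
        "mode": c.feature.mode,
        "label_class": c.label_class,
        "rho_vs_reference": c.rho,
        "al_el_asymmetry": c.asymmetry,
        "reason": c.reason,
    } for c in classifications])
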