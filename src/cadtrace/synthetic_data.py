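"""Synthetic dual-mode LC-MS feature tables with known ground truth.

The generator emulates an isotope-tracing study of an engineered metabolic
pathway in *Arabidopsis*: transgenic lines expressing a lysine decarboxylase
accumulate cadaverine and cadaverine-derived metabolites that are absent from
the wild type.  Feeding [alpha-15N]- or [epsilon-15N]-lysine (treatments AL
and EL) labels one nitrogen of cadaverine; because cadaverine is symmetric,
metabolites that retain both of its nitrogens inherit the full cadaverine
labeling fraction while metabolites that lose one nitrogen inherit half of
it, regardless of which lysine isotopomer was fed.  A non-labeled feeding
(NL) provides the natural-abundance baseline.

For every compound and chromatographic mode the generator emits a
monoisotopic feature (M) and, when labeling treatments are simulated, a
heavy-isotopologue feature (M+1) shifted by the 15N-14N mass difference.
Only nitrogen isotopes populate the M+1 channel — the paired-ion search this
data feeds targets the 15N shift specifically — and each labeled molecule
carries exactly one heavy nitrogen, so there is no M+2 channel.  Intensities
receive multiplicative log-normal noise and are censored to 0 below the
per-mode detection threshold, mimicking the aligner's intensity cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .feature_core import (DEFAULT_THRESHOLDS, FeatureID, FeatureMatrix,
                           MZ_DECIMALS, SampleMeta)

# -- physical constants ----------------------------------------------------

#: Mass of a proton (Da), for the [M+H]+ adduct.
PROTON_MASS = 1.007276466

#: 15N - 14N monoisotopic mass difference (Da); printed as 0.997 at 3 d.p.
DELTA_15N = 0.9970349

#: Natural terrestrial abundance of 15N.
NATURAL_15N_ABUNDANCE = 0.00364

_SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "S", "P")

#: Retention-time span of each chromatographic gradient (minutes).
GRADIENT_SPAN = {"RP": 40.0, "HI": 50.0}

LABEL_CLASSES = ("both_nitrogens_from_cadaverine", "one_nitrogen_from_cadaverine",
                 "alpha_nitrogen_only", "unlabeled_background")


class SimulationError(ValueError):
    """Raised for invalid formulas, compound specs or scenarios."""


# -- formulas and masses ---------------------------------------------------


@dataclass(frozen=True)
class Formula:
    """An elemental formula over C, H, N, O, S, P with positive counts."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise SimulationError("formula must contain at least one element")
        for element, n in self.counts.items():
            if element not in _SUPPORTED_ELEMENTS:
                raise SimulationError(
                    f"unsupported element {element!r}; supported: {_SUPPORTED_ELEMENTS}"
                )
            if not isinstance(n, int) or n < 1:
                raise SimulationError(f"count for {element} must be a positive integer")
        object.__setattr__(self, "counts", dict(self.counts))

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``C5H14N2``."""
        import re
        counts: dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if m.group(0) == "":
                continue
            if m.start() != pos:
                raise SimulationError(f"cannot parse formula {text!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text) or not counts:
            raise SimulationError(f"cannot parse formula {text!r}")
        return cls(counts)

    @property
    def n_nitrogen(self) -> int:
        return self.counts.get("N", 0)

    def to_string(self) -> str:
        order = [e for e in ("C", "H", "N", "O", "S", "P") if e in self.counts]
        return "".join(f"{e}{self.counts[e] if self.counts[e] > 1 else ''}" for e in order)


def monoisotopic_mass(formula: Formula | str) -> float:
    """Monoisotopic mass (Da) of a neutral formula."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    return float(_ptmass.calculate_mass(composition=dict(formula.counts)))


def protonated_mz(formula: Formula | str) -> float:
    """m/z of the [M+H]+ adduct (positive-ion electrospray)."""
    return monoisotopic_mass(formula) + PROTON_MASS


def natural_heavy_fraction(n_nitrogen: int, a: float = NATURAL_15N_ABUNDANCE) -> float:
    """Probability that a molecule with ``n_nitrogen`` N atoms carries >=1 15N.

    1 - (1-a)^n under independent natural incorporation.  Isotopes of other
    elements are deliberately excluded: the M+1 pair search downstream
    targets the 15N-14N shift only.
    """
    if n_nitrogen < 0:
        raise SimulationError("n_nitrogen must be >= 0")
    if not 0 <= a < 1:
        raise SimulationError("abundance must be in [0, 1)")
    return 1.0 - (1.0 - a) ** n_nitrogen


# -- compound panel and scenario ------------------------------------------


@dataclass(frozen=True)
class CompoundSpec:
    """One simulated compound: chemistry, chromatography and genotype biology.

    ``base_abundance`` is either a scalar (per-genotype scaling then follows
    ``transgene_dependent``) or a mapping genotype -> abundance that is used
    verbatim.  Transgene-dependent compounds scale linearly with the
    genotype's transgene-expression level and are therefore absent from the
    wild type (expression 0).
    """

    compound_id: str
    formula: Formula
    mode_presence: tuple[str, ...]
    rt_per_mode: Mapping[str, float]
    base_abundance: float | Mapping[str, float]
    label_class: str = "unlabeled_background"
    pathway_ids: tuple[str, ...] = ()
    transgene_dependent: bool | None = None

    def __post_init__(self) -> None:
        if self.label_class not in LABEL_CLASSES:
            raise SimulationError(f"unknown label_class {self.label_class!r}")
        if not self.mode_presence:
            raise SimulationError(f"{self.compound_id}: empty mode_presence")
        for mode in self.mode_presence:
            if mode not in GRADIENT_SPAN:
                raise SimulationError(f"{self.compound_id}: unknown mode {mode!r}")
            rt = self.rt_per_mode.get(mode)
            if rt is None or not 0 <= rt <= GRADIENT_SPAN[mode]:
                raise SimulationError(
                    f"{self.compound_id}: rt for {mode} must lie in "
                    f"[0, {GRADIENT_SPAN[mode]}] min"
                )
        if isinstance(self.base_abundance, Mapping):
            if any(v < 0 for v in self.base_abundance.values()):
                raise SimulationError(f"{self.compound_id}: abundance must be >= 0")
        elif self.base_abundance < 0:
            raise SimulationError(f"{self.compound_id}: abundance must be >= 0")
        n = self.formula.n_nitrogen
        if self.label_class == "both_nitrogens_from_cadaverine" and n < 2:
            raise SimulationError(f"{self.compound_id}: both-nitrogen compounds need >= 2 N")
        if self.label_class == "one_nitrogen_from_cadaverine" and n != 1:
            raise SimulationError(f"{self.compound_id}: one-nitrogen compounds need exactly 1 N")
        object.__setattr__(self, "mode_presence", tuple(self.mode_presence))
        object.__setattr__(self, "rt_per_mode", dict(self.rt_per_mode))
        object.__setattr__(self, "pathway_ids", tuple(self.pathway_ids))

    @property
    def is_transgene_dependent(self) -> bool:
        if self.transgene_dependent is not None:
            return self.transgene_dependent
        return self.label_class != "unlabeled_background"

    def tracer_fraction(self, treatment: str, p_lys: float, p_cad: float) -> float:
        """Fraction of molecules carrying one tracer 15N under a treatment."""
        if treatment in ("NL", "none"):
            return 0.0
        if self.label_class == "both_nitrogens_from_cadaverine":
            return p_cad
        if self.label_class == "one_nitrogen_from_cadaverine":
            # symmetric cadaverine: the single retained nitrogen is the
            # labeled one with probability 1/2 under either isotopomer
            return p_cad / 2.0
        if self.label_class == "alpha_nitrogen_only":
            return p_lys if treatment == "AL" else 0.0
        return 0.0


@dataclass(frozen=True)
class SimulationScenario:
    """Study design and generative parameters.

    Defaults follow the source study design: wild type plus three transgenic
    lines with graded transgene expression (relative levels 1 : 3 : 7.7),
    three biological replicates, aligner cut-offs 8000 (RP) / 3000 (HI).
    """

    genotypes: tuple[tuple[str, float], ...] = (
        ("Col-0", 0.0), ("DC42", 1.0), ("DC21", 3.0), ("DC29", 7.7))
    treatments: tuple[str, ...] = ("none",)
    replicates_per_group: int = 3
    p_lys: float = 0.935
    p_cad: float = 0.6
    natural_15n_abundance: float = NATURAL_15N_ABUNDANCE
    noise_cv: float = 0.1
    detection_threshold: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise SimulationError("at least one genotype required")
        if any(expr < 0 for _, expr in self.genotypes):
            raise SimulationError("transgene expression must be >= 0")
        for t in self.treatments:
            if t not in ("AL", "EL", "NL", "none"):
                raise SimulationError(f"unknown treatment {t!r}")
        if self.replicates_per_group < 2:
            raise SimulationError("need >= 2 replicates per group")
        if not 0 <= self.p_lys <= 1 or not 0 <= self.p_cad <= 1:
            raise SimulationError("tracer fractions must lie in [0, 1]")
        if self.p_cad > self.p_lys:
            raise SimulationError("p_cad cannot exceed p_lys "
                                  "(cadaverine is made from the fed lysine)")
        if not 0 <= self.natural_15n_abundance < 1:
            raise SimulationError("natural abundance must be in [0, 1)")
        if self.noise_cv < 0:
            raise SimulationError("noise_cv must be >= 0")
        if self.noise_cv > 0 and self.seed is None:
            raise SimulationError("a seed is required when noise_cv > 0")
        if any(v <= 0 for v in self.detection_threshold.values()):
            raise SimulationError("detection thresholds must be > 0")
        object.__setattr__(self, "genotypes", tuple((g, float(e)) for g, e in self.genotypes))
        object.__setattr__(self, "treatments", tuple(self.treatments))
        object.__setattr__(self, "detection_threshold", dict(self.detection_threshold))

    @property
    def labeling_on(self) -> bool:
        return any(t in ("AL", "EL", "NL") for t in self.treatments)

    def sample_plan(self) -> list[SampleMeta]:
        out = []
        for genotype, _ in self.genotypes:
            for treatment in self.treatments:
                for rep in range(1, self.replicates_per_group + 1):
                    out.append(SampleMeta(f"{genotype}_{treatment}_r{rep}",
                                          genotype, treatment, rep))
        return out


# -- the generator ---------------------------------------------------------


def simulate_feature_tables(
    scenario: SimulationScenario,
    panel: Sequence[CompoundSpec],
) -> tuple[dict[str, FeatureMatrix], pd.DataFrame]:
    """Simulate per-mode feature matrices plus a per-feature truth table.

    Returns ``(matrices, ground_truth)`` where ``matrices`` maps mode ->
    FeatureMatrix and ``ground_truth`` has one row per emitted feature with
    its source compound, isotopologue role (M or M+1), differential class
    and true tracer fraction per treatment.  Identical scenario + seed give
    identical output.
    """
    if not panel:
        raise SimulationError("compound panel is empty")
    ids = [c.compound_id for c in panel]
    if len(set(ids)) != len(ids):
        raise SimulationError("duplicate compound ids in panel")
    rng = np.random.default_rng(scenario.seed)
    sigma = float(np.sqrt(np.log1p(scenario.noise_cv ** 2)))
    samples = scenario.sample_plan()
    expression = dict(scenario.genotypes)
    a = scenario.natural_15n_abundance

    matrices: dict[str, FeatureMatrix] = {}
    truth_rows: list[dict] = []
    modes = sorted({m for c in panel for m in c.mode_presence})
    for mode in modes:
        features: list[FeatureID] = []
        rows: list[np.ndarray] = []
        for compound in panel:
            if mode not in compound.mode_presence:
                continue
            mz_light = round(protonated_mz(compound.formula), MZ_DECIMALS)
            rt = compound.rt_per_mode[mode]
            roles = [("M", mz_light)]
            if scenario.labeling_on:
                roles.append(("M+1", round(mz_light + DELTA_15N, MZ_DECIMALS)))
            nat = natural_heavy_fraction(compound.formula.n_nitrogen, a)
            role_rows = {role: np.zeros(len(samples)) for role, _ in roles}
            for j, s in enumerate(samples):
                abundance = _abundance_for(compound, s.genotype, expression)
                f_trace = compound.tracer_fraction(s.treatment, scenario.p_lys,
                                                   scenario.p_cad)
                f_obs = f_trace + (1.0 - f_trace) * nat
                channel = {"M": abundance * (1.0 - f_obs), "M+1": abundance * f_obs}
                for role, _ in roles:
                    value = channel[role]
                    if scenario.noise_cv > 0 and value > 0:
                        value *= float(rng.lognormal(-0.5 * sigma ** 2, sigma))
                    role_rows[role][j] = value
            for role, mz in roles:
                fid = FeatureID.make(mode, rt, mz)
                features.append(fid)
                rows.append(role_rows[role])
                truth_rows.append({
                    "feature_id": fid.render(),
                    "mode": mode,
                    "compound_id": compound.compound_id,
                    "role": role,
                    "label_class": compound.label_class,
                    "n_nitrogen": compound.formula.n_nitrogen,
                    "differential_class": _differential_class(compound, expression),
                    "f_trace_AL": compound.tracer_fraction("AL", scenario.p_lys,
                                                           scenario.p_cad),
                    "f_trace_EL": compound.tracer_fraction("EL", scenario.p_lys,
                                                           scenario.p_cad),
                    "f_trace_NL": 0.0,
                })
        intensities = np.vstack(rows) if rows else np.zeros((0, len(samples)))
        thr = scenario.detection_threshold.get(mode, DEFAULT_THRESHOLDS[mode])
        intensities = np.where(intensities < thr, 0.0, intensities)
        matrices[mode] = FeatureMatrix(features, samples, intensities,
                                       scenario.detection_threshold)
    truth = pd.DataFrame(truth_rows)
    return matrices, truth


def _abundance_for(compound: CompoundSpec, genotype: str,
                   expression: Mapping[str, float]) -> float:
    if isinstance(compound.base_abundance, Mapping):
        try:
            return float(compound.base_abundance[genotype])
        except KeyError:
            raise SimulationError(
                f"{compound.compound_id}: no abundance for genotype {genotype!r}"
            ) from None
    base = float(compound.base_abundance)
    if compound.is_transgene_dependent:
        return base * expression[genotype]
    return base


def _differential_class(compound: CompoundSpec,
                        expression: Mapping[str, float]) -> str:
    """Truth label: transgenic-associated / control-associated / null."""
    if isinstance(compound.base_abundance, Mapping):
        case, control = [], []
        for genotype, expr in expression.items():
            value = float(compound.base_abundance.get(genotype, 0.0))
            (control if expr == 0 else case).append(value)
        if not case or not control:
            return "null"
        mean_case = float(np.mean(case))
        mean_control = float(np.mean(control))
        if mean_case > 1.5 * mean_control:
            return "transgenic-associated"
        if mean_control > 1.5 * mean_case:
            return "control-associated"
        return "null"
    return "transgenic-associated" if compound.is_transgene_dependent else "null"


# -- bundled panels and scenarios -----------------------------------------


def default_panel(base_abundance: float = 3.0e6,
                  background_abundance: float = 8.0e5) -> list[CompoundSpec]:
    """The cadaverine catabolic pathway panel plus wild-type background.

    Pathway compounds (absent from the wild type): cadaverine and its
    catabolites / conjugates; retention times follow the printed feature
    names of the study this generator emulates.  Background compounds are
    constitutive metabolites present in every genotype.
    """
    F = Formula.parse
    return [
        CompoundSpec("cadaverine", F("C5H14N2"), ("RP", "HI"),
                     {"RP": 1.63, "HI": 24.0}, base_abundance,
                     "both_nitrogens_from_cadaverine", ("map00330", "map01064")),
        CompoundSpec("5-aminopentanal", F("C5H11NO"), ("RP", "HI"),
                     {"RP": 2.34, "HI": 10.3}, 0.6 * base_abundance,
                     "one_nitrogen_from_cadaverine", ("map01064",)),
        CompoundSpec("5-aminopentanoate", F("C5H11NO2"), ("HI",),
                     {"HI": 11.21}, 0.5 * base_abundance,
                     "one_nitrogen_from_cadaverine", ("map00310",)),
        CompoundSpec("delta-valerolactam", F("C5H9NO"), ("RP",),
                     {"RP": 9.23}, 0.4 * base_abundance,
                     "one_nitrogen_from_cadaverine", ("map00960",)),
        CompoundSpec("N-acetylcadaverine", F("C7H16N2O"), ("RP", "HI"),
                     {"RP": 2.39, "HI": 11.43}, 0.7 * base_abundance,
                     "both_nitrogens_from_cadaverine", ("map00330",)),
        CompoundSpec("p-coumaroylcadaverine", F("C14H20N2O2"), ("HI",),
                     {"HI": 6.9}, 0.3 * base_abundance,
                     "both_nitrogens_from_cadaverine", ("map00940",)),
        CompoundSpec("alpha-regiospecific-unknown", F("C5H7NO6"), ("HI",),
                     {"HI": 11.19}, 0.5 * base_abundance,
                     "alpha_nitrogen_only", ()),
        # constitutive background, present in all genotypes
        CompoundSpec("l-lysine", F("C6H14N2O2"), ("RP", "HI"),
                     {"RP": 1.70, "HI": 25.59}, background_abundance,
                     "unlabeled_background", ("map00310",)),
        CompoundSpec("l-ornithine", F("C5H12N2O2"), ("HI",),
                     {"HI": 25.57}, background_abundance,
                     "unlabeled_background", ("map00330",)),
        CompoundSpec("putrescine", F("C4H12N2"), ("HI",),
                     {"HI": 24.75}, background_abundance,
                     "unlabeled_background", ("map00330",)),
        CompoundSpec("gaba", F("C4H9NO2"), ("HI",),
                     {"HI": 12.4}, background_abundance,
                     "unlabeled_background", ("map00330",)),
    ]


def benchmark_panel(n_differential: int = 20, n_background: int = 480,
                    seed: int = 0) -> list[CompoundSpec]:
    """A differential-selection benchmark: planted markers among null features.

    ``n_differential`` transgene-dependent compounds (absent from the wild
    type, scaling with transgene expression) are hidden among
    ``n_background`` constitutive compounds whose base abundances span two
    decades, as in real untargeted matrices.  One mode per compound,
    alternating, with randomized retention times and formulas.
    """
    rng = np.random.default_rng(seed)
    panel: list[CompoundSpec] = []
    for k in range(n_differential + n_background):
        differential = k < n_differential
        counts = {"C": int(rng.integers(4, 20)), "H": int(rng.integers(6, 32)),
                  "N": int(rng.integers(1, 4)), "O": int(rng.integers(1, 7))}
        mode = "RP" if k % 2 == 0 else "HI"
        rt = float(rng.uniform(1.0, GRADIENT_SPAN[mode] - 1.0))
        abundance = float(10 ** rng.uniform(4.7, 6.3))
        if differential:
            spec = CompoundSpec(f"marker{k:03d}", Formula(counts), (mode,),
                                {mode: rt}, abundance,
                                "both_nitrogens_from_cadaverine"
                                if counts["N"] >= 2 else "one_nitrogen_from_cadaverine"
                                if counts["N"] == 1 else "unlabeled_background",
                                ("map_bench",), transgene_dependent=True)
        else:
            spec = CompoundSpec(f"bg{k:03d}", Formula(counts), (mode,),
                                {mode: rt}, abundance, "unlabeled_background")
        panel.append(spec)
    return panel


def tracing_scenario(seed: int, p_cad: float = 0.6, noise_cv: float = 0.1,
                     p_lys: float = 0.935) -> SimulationScenario:
    """Feeding-experiment design: the high-expressing line under AL/EL/NL."""
    return SimulationScenario(genotypes=(("DC29", 7.7),),
                              treatments=("AL", "EL", "NL"),
                              replicates_per_group=3,
                              p_lys=p_lys, p_cad=p_cad,
                              noise_cv=noise_cv, seed=seed)


def profiling_scenario(seed: int, noise_cv: float = 0.2) -> SimulationScenario:
    """Untargeted-profiling design: four genotypes, no feeding."""
    return SimulationScenario(treatments=("none",), replicates_per_group=3,
                              noise_cv=noise_cv, seed=seed)


def write_ground_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
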