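"""Accurate-mass compound annotation and pathway over-representation testing.

Features are matched to library compounds by the relative error between the
observed m/z and the theoretical [M+H]+ m/z (default tolerance 10 ppm); the
annotated differential set is then tested per pathway for enrichment against
an annotated background with the one-sided Fisher's exact (hypergeometric
tail) test, significance at raw P < 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from scipy import stats

from .feature_core import FeatureID
from .synthetic_data import Formula, protonated_mz


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str
    formula: Formula
    mz: float                      # theoretical [M+H]+
    pathway_ids: tuple[str, ...]


@dataclass
class CompoundLibrary:
    """Pathway-annotated compound records with precomputed [M+H]+ m/z."""

    records: list[CompoundRecord]
    pathway_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise AnnotationError("duplicate compound ids in library")

    @classmethod
    def from_table(cls, df: pd.DataFrame,
                   pathway_names: dict[str, str] | None = None) -> "CompoundLibrary":
        records = []
        for row in df.itertuples():
            formula = Formula.parse(str(row.formula))
            pathways = tuple(p for p in str(row.pathway_ids).split(";") if p and p != "nan")
            records.append(CompoundRecord(str(row.compound_id), str(row.name_),
                                          formula, protonated_mz(formula), pathways))
        return cls(records, pathway_names or {})

    @classmethod
    def from_tsv(cls, path: str) -> "CompoundLibrary":
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.rename(columns={"name": "name_"})
        return cls.from_table(df)

    @classmethod
    def bundled(cls) -> "CompoundLibrary":
        """The compound library shipped with the package (synthetic curation
        of the cadaverine/putrescine pathway neighbourhood and common plant
        metabolites)."""
        ref = resources.files("cadtrace").joinpath("data/compound_library.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(str(path))

    def pathway_catalogue(self) -> dict[str, set[str]]:
        catalogue: dict[str, set[str]] = {}
        for rec in self.records:
            for pid in rec.pathway_ids:
                catalogue.setdefault(pid, set()).add(rec.compound_id)
        return catalogue


@dataclass(frozen=True)
class AnnotationParams:
    ppm_tolerance: float = 10.0

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0:
            raise AnnotationError("ppm tolerance must be > 0")


@dataclass(frozen=True)
class AnnotationMatch:
    compound: CompoundRecord
    ppm_error: float


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


def annotate(features: list[FeatureID], library: CompoundLibrary,
             params: AnnotationParams = AnnotationParams()
             ) -> dict[FeatureID, list[AnnotationMatch]]:
    """Match features to library compounds within the ppm tolerance.

    Every compound with |relative m/z error| < tolerance is retained, nearest
    first; features with no match are absent from the result.  The outcome is
    independent of library record order.
    """
    out: dict[FeatureID, list[AnnotationMatch]] = {}
    for feature in features:
        matches = []
        for rec in library.records:
            err = ppm_error(feature.mz, rec.mz)
            if abs(err) < params.ppm_tolerance:
                matches.append(AnnotationMatch(rec, err))
        if matches:
            matches.sort(key=lambda m: (abs(m.ppm_error), m.compound.compound_id))
            out[feature] = matches
    return out


def annotated_compound_set(annotations: dict[FeatureID, list[AnnotationMatch]]) -> set[str]:
    """Compound-level deduplication: each matched compound counts once."""
    return {m.compound.compound_id for ms in annotations.values() for m in ms}


@dataclass(frozen=True)
class EnrichmentTestResult:
    pathway_id: str
    a: int   # differential ∩ pathway
    b: int   # differential \ pathway
    c: int   # non-differential background ∩ pathway
    d: int   # non-differential background \ pathway
    p_value: float
    significant: bool
    note: str = ""


def fisher_enrichment(differential: set[str], background: set[str],
                      pathway_catalogue: dict[str, set[str]],
                      alpha: float = 0.05) -> list[EnrichmentTestResult]:
    """One-sided pathway over-representation on annotated compound sets.

    ``differential`` must be a subset of ``background``.  Per pathway the
    2x2 table is (a, b; c, d) with a = differential pathway members and the
    complement rows drawn from ``background - differential``; the p-value is
    the hypergeometric upper tail P(X >= a) under fixed margins.  Pathways
    with no background members are skipped with a note.  Results sorted by p.
    """
    if not differential <= background:
        raise AnnotationError("differential set must be a subset of the background")
    rest = background - differential
    results = []
    for pid in sorted(pathway_catalogue):
        members = pathway_catalogue[pid]
        in_bg = members & background
        if not in_bg:
            results.append(EnrichmentTestResult(pid, 0, len(differential), 0,
                                                len(rest), 1.0, False,
                                                "no background members; skipped"))
            continue
        a = len(members & differential)
        b = len(differential) - a
        c = len(members & rest)
        d = len(rest) - c
        # P(X >= a) for X ~ Hypergeom(M=a+b+c+d, n=a+c, N=a+b)
        p = float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
        results.append(EnrichmentTestResult(pid, a, b, c, d, p, p < alpha))
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def enrichment_table(results: list[EnrichmentTestResult],
                     bh_correct: bool = False) -> pd.DataFrame:
    """Tabulate enrichment results; optional Benjamini-Hochberg column."""
    df = pd.DataFrame([{"pathway": r.pathway_id, "a": r.a, "b": r.b, "c": r.c,
                        "d": r.d, "p_value": r.p_value,
                        "significant": r.significant, "note": r.note}
                       for r in results])
    if bh_correct and len(df):
        from statsmodels.stats.multitest import multipletests  # optional path
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
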