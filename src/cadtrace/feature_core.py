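"""Aligned LC-MS feature matrices: data model, naming convention and TSV I/O.

An untargeted metabolomics experiment profiled in two chromatographic modes
(reversed-phase, ``RP``, and hydrophilic interaction, ``HI``) yields one
aligned feature matrix per mode.  Each feature is named by its mode, retention
time and m/z — e.g. ``RP_1.63/103.1233`` — and each sample carries genotype,
feeding-treatment and replicate metadata.  Missing values are encoded as 0
(the alignment tool's convention), and a per-mode intensity cut-off defines
detection: 8000 for RP, 3000 for HI by default.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MODES = ("RP", "HI")

#: Default per-mode intensity cut-offs for calling a feature "detected".
DEFAULT_THRESHOLDS: dict[str, float] = {"RP": 8000.0, "HI": 3000.0}

#: Feeding treatments: [alpha-15N]-lysine, [epsilon-15N]-lysine, non-labeled
#: lysine, or no feeding at all.
TREATMENTS = ("AL", "EL", "NL", "none")

#: Decimal places used when a feature ID is rendered at creation time.
RT_DECIMALS = 2
MZ_DECIMALS = 4

_FEATURE_ID_RE = re.compile(r"^(?P<mode>[A-Z]{2})_(?P<rt>\d+(?:\.\d+)?)/(?P<mz>\d+(?:\.\d+)?)$")


class FeatureMatrixError(ValueError):
    """Raised for malformed feature matrices or feature IDs."""


@dataclass(frozen=True, order=True)
class FeatureID:
    """A feature named ``<mode>_<rt>/<mz>``, e.g. ``RP_1.63/103.1233``.

    ``rt_str``/``mz_str`` preserve the printed decimal precision so that
    parse-then-render is the identity; ``rt``/``mz`` are the numeric values.
    """

    mode: str
    rt_str: str
    mz_str: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise FeatureMatrixError(
                f"unknown chromatography mode {self.mode!r}; expected one of {MODES}"
            )
        if self.rt < 0:
            raise FeatureMatrixError(f"negative retention time in {self!r}")
        if self.mz <= 0:
            raise FeatureMatrixError(f"non-positive m/z in {self!r}")

    @property
    def rt(self) -> float:
        return float(self.rt_str)

    @property
    def mz(self) -> float:
        return float(self.mz_str)

    @classmethod
    def make(cls, mode: str, rt: float, mz: float,
             rt_decimals: int = RT_DECIMALS, mz_decimals: int = MZ_DECIMALS) -> "FeatureID":
        """Build an ID from numeric rt/mz, applying the creation-time rounding."""
        return cls(mode, f"{rt:.{rt_decimals}f}", f"{mz:.{mz_decimals}f}")

    @classmethod
    def parse(cls, text: str) -> "FeatureID":
        m = _FEATURE_ID_RE.match(text.strip())
        if m is None:
            bad_mode = text.split("_", 1)[0]
            if bad_mode not in MODES:
                raise FeatureMatrixError(
                    f"cannot parse feature ID {text!r}: bad mode token {bad_mode!r}"
                )
            raise FeatureMatrixError(f"cannot parse feature ID {text!r}")
        return cls(m.group("mode"), m.group("rt"), m.group("mz"))

    def render(self) -> str:
        return f"{self.mode}_{self.rt_str}/{self.mz_str}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class SampleMeta:
    """One biological replicate: genotype × treatment × replicate index."""

    sample_id: str
    genotype: str
    treatment: str = "none"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise FeatureMatrixError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        if self.replicate < 1:
            raise FeatureMatrixError("replicate index must be >= 1")


class FeatureMatrix:
    """Intensities of aligned features (rows) over annotated samples (columns).

    Intensities are non-negative reals; 0 means "not detected by the aligner".
    """

    def __init__(self, features: Iterable[FeatureID], samples: Iterable[SampleMeta],
                 intensities: np.ndarray,
                 thresholds: Mapping[str, float] | None = None) -> None:
        self.features: list[FeatureID] = list(features)
        self.samples: list[SampleMeta] = list(samples)
        self.intensities = np.asarray(intensities, dtype=float)
        self.thresholds = dict(thresholds) if thresholds is not None else dict(DEFAULT_THRESHOLDS)
        self._validate()
        self._feature_index = {f: i for i, f in enumerate(self.features)}
        self._sample_index = {s.sample_id: j for j, s in enumerate(self.samples)}

    def _validate(self) -> None:
        n, m = len(self.features), len(self.samples)
        if self.intensities.shape != (n, m):
            raise FeatureMatrixError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{n} features x {m} samples"
            )
        if len(set(self.features)) != n:
            raise FeatureMatrixError("duplicate feature IDs")
        keys = [(s.genotype, s.treatment, s.replicate) for s in self.samples]
        if len(set(keys)) != m:
            raise FeatureMatrixError("duplicate (genotype, treatment, replicate) sample keys")
        if len({s.sample_id for s in self.samples}) != m:
            raise FeatureMatrixError("duplicate sample IDs")
        if np.any(~np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise FeatureMatrixError("intensities must be finite and non-negative")
        for thr in self.thresholds.values():
            if thr <= 0:
                raise FeatureMatrixError("detection thresholds must be > 0")

    # -- lookups ----------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def feature_index(self, feature: FeatureID | str) -> int:
        if isinstance(feature, str):
            feature = FeatureID.parse(feature)
        try:
            return self._feature_index[feature]
        except KeyError:
            raise FeatureMatrixError(f"unknown feature {feature.render()}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise FeatureMatrixError(f"unknown sample {sample_id!r}") from None

    def intensity(self, feature: FeatureID | str, sample_id: str) -> float:
        return float(self.intensities[self.feature_index(feature), self.sample_index(sample_id)])

    def detected(self, feature: FeatureID | str, sample_id: str) -> bool:
        """True iff intensity >= the mode's cut-off (threshold inclusive)."""
        i = self.feature_index(feature)
        j = self.sample_index(sample_id)
        mode = self.features[i].mode
        return bool(self.intensities[i, j] >= self.thresholds[mode])

    def detection_mask(self) -> np.ndarray:
        """Boolean features x samples matrix of the inclusive threshold rule."""
        thr = np.array([self.thresholds[f.mode] for f in self.features])
        return self.intensities >= thr[:, None]

    def subset_samples(self, keep: Iterable[str]) -> "FeatureMatrix":
        keep = list(keep)
        idx = [self.sample_index(s) for s in keep]
        return FeatureMatrix(self.features, [self.samples[j] for j in idx],
                             self.intensities[:, idx], self.thresholds)

    def subset_features(self, keep: Iterable[FeatureID]) -> "FeatureMatrix":
        idx = [self.feature_index(f) for f in keep]
        return FeatureMatrix([self.features[i] for i in idx], self.samples,
                             self.intensities[idx, :], self.thresholds)

    def samples_for(self, genotype: str | None = None,
                    treatment: str | None = None) -> list[SampleMeta]:
        out = []
        for s in self.samples:
            if genotype is not None and s.genotype != genotype:
                continue
            if treatment is not None and s.treatment != treatment:
                continue
            out.append(s)
        return out

    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.genotype, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities,
                            index=[f.render() for f in self.features],
                            columns=[s.sample_id for s in self.samples])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (self.features == other.features and self.samples == other.samples
                and self.thresholds == other.thresholds
                and np.array_equal(self.intensities, other.intensities))


# -- TSV I/O ---------------------------------------------------------------
#
# Dialect: UTF-8, tab-delimited, '#'-prefixed comment lines ignored.  The
# matrix file has a header row "feature_id<TAB>sample1<TAB>..." followed by
# one row per feature.  Sample metadata travels in a sidecar TSV with columns
# sample_id, genotype, treatment, replicate.  Thresholds are recorded as
# "# threshold <mode> <value>" comment lines in the matrix file.


def _strip_comments(path: str) -> tuple[str, dict[str, float], list[tuple[int, str]]]:
    thresholds: dict[str, float] = {}
    kept: list[str] = []
    line_numbers: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 3 and parts[0] == "threshold":
                    thresholds[parts[1]] = float(parts[2])
                continue
            if line.strip() == "":
                continue
            kept.append(line)
            line_numbers.append((lineno, line))
    return "".join(kept), thresholds, line_numbers


def write_matrix(matrix: FeatureMatrix, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mode in sorted(matrix.thresholds):
            fh.write(f"# threshold {mode} {matrix.thresholds[mode]:g}\n")
        fh.write("feature_id\t" + "\t".join(s.sample_id for s in matrix.samples) + "\n")
        for i, f in enumerate(matrix.features):
            row = "\t".join(_format_intensity(v) for v in matrix.intensities[i])
            fh.write(f.render() + "\t" + row + "\n")


def _format_intensity(v: float) -> str:
    return repr(float(v))


def read_matrix(path: str, meta_path: str | None = None,
                samples: Iterable[SampleMeta] | None = None) -> FeatureMatrix:
    """Read a feature matrix TSV; metadata from ``meta_path`` or ``samples``.

    Malformed feature IDs are rejected with their line number.
    """
    text, thresholds, line_numbers = _strip_comments(path)
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
    features = []
    for k, fid in enumerate(df.index):
        try:
            features.append(FeatureID.parse(str(fid)))
        except FeatureMatrixError as exc:
            lineno = line_numbers[k + 1][0] if k + 1 < len(line_numbers) else "?"
            raise FeatureMatrixError(f"line {lineno}: {exc}") from None
    values = df.to_numpy(dtype=float)
    if samples is not None:
        sample_list = list(samples)
    elif meta_path is not None:
        sample_list = read_sample_meta(meta_path)
    else:
        raise FeatureMatrixError("sample metadata required (meta_path or samples)")
    by_id = {s.sample_id: s for s in sample_list}
    try:
        ordered = [by_id[c] for c in df.columns]
    except KeyError as exc:
        raise FeatureMatrixError(f"sample {exc.args[0]!r} missing from metadata") from None
    return FeatureMatrix(features, ordered, values,
                         thresholds if thresholds else None)


def write_sample_meta(samples: Iterable[SampleMeta], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgenotype\ttreatment\treplicate\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.genotype}\t{s.treatment}\t{s.replicate}\n")


def read_sample_meta(path: str) -> list[SampleMeta]:
    text, _, _ = _strip_comments(path)
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    required = {"sample_id", "genotype", "treatment", "replicate"}
    if not required.issubset(df.columns):
        raise FeatureMatrixError(
            f"sample metadata must have columns {sorted(required)}; got {list(df.columns)}"
        )
    return [SampleMeta(r.sample_id, r.genotype, r.treatment, int(r.replicate))
            for r in df.itertuples()]
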