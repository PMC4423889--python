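"""Data model and I/O for nCounter-style miRNA count panels.

The panel mixes endogenous probes (human ``hsa-`` miRNAs and herpesvirus-family
viral miRNAs), positive-control and negative-control probes.  Counts travel as a
plain CSV: ``probe_id,probe_class,<sample>,<sample>,...``.  Sample metadata is a
second CSV carrying the study design (healthy individuals with repeated
sampling, glioblastoma patients with survival follow-up).

The module also ships the published result lists (differential-expression
candidates, prognostic miRNAs, diagnostic/prognostic overlap, viral
differentials) as machine-readable fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VIRAL_PREFIXES",
    "PROBE_CLASSES",
    "PanelFormatError",
    "ClassificationError",
    "ProbeInfo",
    "CountMatrix",
    "FixtureSet",
    "classify_viral",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_table",
    "write_sample_table",
    "validate_sample_table",
    "load_fixtures",
    "canonical_probe_id",
]

#: Viral species covered by the panel, keyed by probe-id prefix.
VIRAL_PREFIXES: tuple[str, ...] = ("ebv", "hsv1", "hsv2", "kshv", "hcmv")

PROBE_CLASSES = ("endogenous", "positive_control", "negative_control")

SAMPLE_COLUMNS = [
    "sample_id",
    "subject_id",
    "group",
    "replicate_index",
    "age",
    "sex",
    "bmi",
    "survival_time",
    "event",
]


class PanelFormatError(ValueError):
    """Malformed count-matrix or sample-table file."""


class ClassificationError(ValueError):
    """Probe identifier with no recognized species prefix."""


def classify_viral(
    probe_id: str, prefixes: Iterable[str] = VIRAL_PREFIXES
) -> tuple[str, str | None]:
    """Classify a probe id as human or viral by its miRBase-style prefix.

    Returns ``(species, viral_prefix)`` where species is ``"human"`` or
    ``"viral"``.  Unrecognized prefixes raise :class:`ClassificationError`
    rather than defaulting to human, so panel typos surface immediately.
    """
    if not probe_id:
        raise ClassificationError("empty probe id")
    if probe_id.startswith("hsa-"):
        return "human", None
    for prefix in prefixes:
        if probe_id.startswith(prefix + "-"):
            return "viral", prefix
    raise ClassificationError(f"unrecognized species prefix in probe id {probe_id!r}")


@dataclass(frozen=True)
class ProbeInfo:
    """One panel probe: id, assay class, and inferred species."""

    probe_id: str
    probe_class: str
    species: str
    viral_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe_class {self.probe_class!r}")
        if self.species not in ("human", "viral", "control"):
            raise ValueError(f"unknown species {self.species!r}")
        if (self.species == "viral") != (self.viral_prefix is not None):
            raise ValueError("viral_prefix must be set iff species is viral")


def _probe_frame(probes: Iterable[ProbeInfo]) -> pd.DataFrame:
    rows = [(p.probe_id, p.probe_class, p.species, p.viral_prefix) for p in probes]
    frame = pd.DataFrame(
        rows, columns=["probe_id", "probe_class", "species", "viral_prefix"]
    ).set_index("probe_id")
    return frame


@dataclass
class CountMatrix:
    """Raw probe-by-sample counts plus probe annotation.

    ``probes`` is indexed by probe_id with columns probe_class / species /
    viral_prefix; ``counts`` shares that index, one integer column per sample.
    """

    probes: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if isinstance(self.probes, (list, tuple)):
            self.probes = _probe_frame(self.probes)
        if not self.probes.index.equals(self.counts.index):
            raise PanelFormatError("probe annotation and counts disagree on probes")
        if self.probes.index.duplicated().any():
            dup = self.probes.index[self.probes.index.duplicated()][0]
            raise PanelFormatError(f"duplicate probe id {dup!r}")
        if self.counts.columns.duplicated().any():
            raise PanelFormatError("duplicate sample ids")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be nonnegative")

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def ids_of_class(self, probe_class: str) -> pd.Index:
        return self.probes.index[self.probes["probe_class"] == probe_class]

    @property
    def endogenous_ids(self) -> pd.Index:
        return self.ids_of_class("endogenous")

    @property
    def negative_control_ids(self) -> pd.Index:
        return self.ids_of_class("negative_control")

    @property
    def positive_control_ids(self) -> pd.Index:
        return self.ids_of_class("positive_control")

    def subset_probes(self, probe_ids: Iterable[str]) -> "CountMatrix":
        idx = pd.Index(probe_ids)
        return CountMatrix(self.probes.loc[idx].copy(), self.counts.loc[idx].copy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        cols = list(sample_ids)
        return CountMatrix(self.probes.copy(), self.counts[cols].copy())


def _annotate_probe(probe_id: str, probe_class: str) -> tuple[str, str, str | None]:
    if probe_class not in PROBE_CLASSES:
        raise ValueError(f"unknown probe_class {probe_class!r} for {probe_id!r}")
    if probe_class != "endogenous":
        return probe_class, "control", None
    species, prefix = classify_viral(probe_id)
    return probe_class, species, prefix


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read the count-matrix CSV dialect (probe_id, probe_class, samples...)."""
    raw = pd.read_csv(path, dtype={"probe_id": str, "probe_class": str})
    expected = ["probe_id", "probe_class"]
    if list(raw.columns[:2]) != expected:
        raise PanelFormatError(
            f"count matrix must start with columns {expected}, got {list(raw.columns[:2])}"
        )
    if raw["probe_id"].duplicated().any():
        dup = raw.loc[raw["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise PanelFormatError(f"duplicate probe id {dup!r}")
    ann = [
        _annotate_probe(pid, cls)
        for pid, cls in zip(raw["probe_id"], raw["probe_class"])
    ]
    probes = pd.DataFrame(
        ann, columns=["probe_class", "species", "viral_prefix"],
        index=pd.Index(raw["probe_id"], name="probe_id"),
    )
    counts = raw.drop(columns=["probe_class"]).set_index("probe_id")
    counts.index.name = "probe_id"
    numeric = counts.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise ValueError("non-numeric count encountered")
    return CountMatrix(probes, numeric)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write the CSV dialect read by :func:`read_count_matrix` (round-trips)."""
    out = matrix.counts.copy()
    out.insert(0, "probe_class", matrix.probes["probe_class"])
    out.reset_index().to_csv(path, index=False, lineterminator="\n")


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate study-design records; returns a normalized copy.

    Healthy-individual (HI) subjects may carry up to three morning replicates;
    survival fields are reserved for glioblastoma patients (GP), and an
    observed event requires a survival time.
    """
    missing = [c for c in SAMPLE_COLUMNS[:7] if c not in table.columns]
    if missing:
        raise PanelFormatError(f"sample table missing columns {missing}")
    out = table.copy()
    for col in ("survival_time", "event"):
        if col not in out.columns:
            out[col] = np.nan
    if out["sample_id"].duplicated().any():
        raise PanelFormatError("duplicate sample ids in sample table")
    bad_group = set(out["group"]) - {"HI", "GP"}
    if bad_group:
        raise ValueError(f"unknown group labels {sorted(bad_group)}")
    if (out["replicate_index"] < 1).any():
        raise ValueError("replicate_index must be >= 1")
    bad_sex = set(out["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"unknown sex labels {sorted(bad_sex)}")

    hi = out[out["group"] == "HI"]
    if hi["survival_time"].notna().any() or hi["event"].notna().any():
        raise ValueError("HI records must not carry survival fields")
    reps = hi.groupby("subject_id")["replicate_index"].nunique()
    if (reps > 3).any():
        raise ValueError("HI subjects have at most 3 replicates")

    gp = out[out["group"] == "GP"]
    event = gp["event"].astype("boolean").fillna(False).astype(bool)
    if (event & gp["survival_time"].isna()).any():
        raise ValueError("event=true requires survival_time")
    if (gp["survival_time"].dropna() < 0).any():
        raise ValueError("survival_time must be nonnegative")
    return out


def read_sample_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    return validate_sample_table(table)


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, lineterminator="\n")


def check_samples_match(matrix: CountMatrix, table: pd.DataFrame) -> None:
    """Cross-check a design table against a count matrix's sample ids."""
    missing = set(matrix.sample_ids) - set(table["sample_id"])
    extra = set(table["sample_id"]) - set(matrix.sample_ids)
    if missing or extra:
        raise PanelFormatError(
            f"sample id mismatch: {sorted(missing)} absent from table, "
            f"{sorted(extra)} absent from counts"
        )


# ---------------------------------------------------------------------------
# Published fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("plasmirna.data").joinpath(name)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path, sep="\t", dtype={"probe_id": str})


@dataclass
class FixtureSet:
    """The published result lists, verbatim and machine-readable.

    table1        : 19 candidate miRNAs (probe_id, logfc, gbm_known, blood_cell)
    prognostic24  : 24 survival-associated miRNAs (20 up, 4 down in long survivors)
    overlap10     : the 10 miRNAs with both diagnostic and prognostic value
    viral11       : the 11 differentially expressed viral miRNAs with direction
    aliases       : printed-spelling -> canonical probe-id map
    """

    table1: pd.DataFrame
    prognostic24: pd.DataFrame
    overlap10: list[str]
    viral11: pd.DataFrame
    aliases: dict[str, str] = field(default_factory=dict)


def load_fixtures() -> FixtureSet:
    table1 = _read_tsv("table1.tsv")
    table1["gbm_known"] = table1["gbm_known"].map({1: True, 0: False})
    table1["blood_cell"] = table1["blood_cell"].astype(int).astype(bool)
    prognostic = _read_tsv("prognostic24.tsv")
    overlap = _read_tsv("overlap10.tsv")["probe_id"].tolist()
    viral = _read_tsv("viral11.tsv")
    viral["viral_prefix"] = [classify_viral(p)[1] for p in viral["probe_id"]]
    alias_frame = _read_tsv("aliases.tsv")
    aliases = dict(zip(alias_frame["alias"], alias_frame["canonical"]))
    return FixtureSet(
        table1=table1,
        prognostic24=prognostic,
        overlap10=overlap,
        viral11=viral,
        aliases=aliases,
    )


def canonical_probe_id(probe_id: str, aliases: Mapping[str, str] | None = None) -> str:
    """Resolve printed spelling variants (e.g. hsv1-miR-H1 vs hsv1-miR-H1-5p)."""
    if aliases is None:
        aliases = load_fixtures().aliases
    return aliases.get(probe_id, probe_id)
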