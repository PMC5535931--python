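"""Experiment-design data model and table I/O for AP-MS spectral-count studies.

An affinity-purification MS (AP-MS) study is described by three tables:

* a *sample manifest* naming each immunoprecipitation (bait, isotype
  control, or pan-methyl pull-down), its treatment condition, its MS run,
  and matched-pair membership;
* one or more *count matrices* (protein groups x samples) holding spectral
  or peptide counts;
* a *peptide evidence* table with peptide sequences, protein-relative
  coordinates, methyl-modification annotations, and identification
  probabilities.

Everything is plain UTF-8 TSV with a header row.  All readers validate
against the manifest; all writers produce deterministic column and row
order so that outputs are diffable and round-trip exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "Antibody",
    "Condition",
    "MethylState",
    "Sample",
    "SampleManifest",
    "CountMatrix",
    "Mod",
    "PeptideEvidence",
    "ContaminantProfile",
    "normalize_peptide",
    "read_manifest",
    "write_manifest",
    "read_count_matrix",
    "write_count_matrix",
    "read_peptide_evidence",
    "read_contaminant_profile",
    "read_gmt",
    "read_edge_list",
    "write_table",
    "read_table",
]


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


class Antibody(str, Enum):
    BAIT = "bait"
    ISOTYPE_CONTROL = "isotype_control"
    PAN_METHYL = "pan_methyl"


class Condition(str, Enum):
    UNTREATED = "untreated"
    TREATED = "treated"


class MethylState(str, Enum):
    """Mono-, di-, or tri-methylation of a Lys/Arg side chain."""

    ME1 = "me1"
    ME2 = "me2"
    ME3 = "me3"


@dataclass(frozen=True)
class Sample:
    sample_id: str
    antibody: Antibody
    condition: Condition
    pair_id: str | None = None
    run_id: str = "run1"


@dataclass(frozen=True)
class SampleManifest:
    """The IP experiment design.

    Invariants enforced at construction: sample ids are unique, every
    matched pair has exactly two members in differing conditions, and at
    least one bait plus one isotype control is present (enrichment over
    background is meaningless otherwise).
    """

    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValidationError("no samples in manifest")
        ids = [s.sample_id for s in self.samples]
        seen: set[str] = set()
        for sid in ids:
            if sid in seen:
                raise ValidationError(f"duplicate sample_id: {sid!r}")
            seen.add(sid)
        pairs: dict[str, list[Sample]] = {}
        for s in self.samples:
            if s.pair_id is not None:
                pairs.setdefault(s.pair_id, []).append(s)
        for pid, members in pairs.items():
            if len(members) != 2:
                raise ValidationError(
                    f"pair {pid!r} has {len(members)} members, expected 2"
                )
            if members[0].condition == members[1].condition:
                raise ValidationError(
                    f"pair {pid!r} members share condition {members[0].condition.value}"
                )
        if not self.bait_samples():
            raise ValidationError("manifest has no bait sample")
        if not self.control_samples():
            raise ValidationError("manifest has no isotype_control sample")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __getitem__(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def bait_samples(self, condition: Condition | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.antibody is Antibody.BAIT
            and (condition is None or s.condition is condition)
        ]

    def control_samples(self) -> list[str]:
        return [
            s.sample_id for s in self.samples if s.antibody is Antibody.ISOTYPE_CONTROL
        ]

    def pan_methyl_samples(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.antibody is Antibody.PAN_METHYL]

    def pairs(self) -> dict[str, tuple[str, str]]:
        """Matched pairs as ``pair_id -> (untreated sample, treated sample)``."""
        out: dict[str, tuple[Sample, Sample]] = {}
        grouped: dict[str, list[Sample]] = {}
        for s in self.samples:
            if s.pair_id is not None:
                grouped.setdefault(s.pair_id, []).append(s)
        result: dict[str, tuple[str, str]] = {}
        for pid, (a, b) in sorted(grouped.items()):
            untx = a if a.condition is Condition.UNTREATED else b
            trt = b if untx is a else a
            result[pid] = (untx.sample_id, trt.sample_id)
        return result

    def condition_of(self, sample_id: str) -> Condition:
        return self[sample_id].condition

    def run_of(self, sample_id: str) -> str:
        return self[sample_id].run_id


@dataclass(frozen=True)
class CountMatrix:
    """Protein-group x sample spectral/peptide counts.

    ``df`` is indexed by protein-group id with sample ids as columns; values
    are nonnegative integers.  ``count_kind`` records which quantitation the
    matrix holds: raw total spectra, exclusive spectra (shared peptides
    removed), or total peptides.
    """

    df: pd.DataFrame
    count_kind: str = "total_spectra"

    _KINDS = ("total_spectra", "exclusive_spectra", "total_peptides")

    def __post_init__(self) -> None:
        if self.count_kind not in self._KINDS:
            raise ValidationError(f"unknown count_kind: {self.count_kind!r}")
        vals = self.df.to_numpy()
        if vals.size:
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.all(np.equal(np.mod(vals, 1), 0)):
                    raise ValidationError("counts must be integral")
            if (vals < 0).any():
                raise ValidationError("counts must be nonnegative")
        if self.df.index.has_duplicates:
            raise ValidationError("duplicate protein ids in count matrix")

    @property
    def proteins(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def subset(self, samples: Sequence[str]) -> pd.DataFrame:
        missing = [s for s in samples if s not in self.df.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return self.df[list(samples)]

    def group_mean(self, samples: Sequence[str]) -> pd.Series:
        """Per-protein mean count over a sample subset."""
        if not samples:
            raise ValidationError("empty sample subset")
        return self.subset(samples).mean(axis=1)


@dataclass(frozen=True)
class Mod:
    """One methyl modification inside a peptide, 1-based offset."""

    offset: int
    residue: str
    state: MethylState

    def __str__(self) -> str:
        return f"{self.residue}{self.offset}:{self.state.value}"


_MOD_RE = re.compile(r"^([A-Z])(\d+):(me[123])$")


def _parse_mods(text: str) -> tuple[Mod, ...]:
    text = text.strip()
    if not text:
        return ()
    mods = []
    for token in text.split(";"):
        m = _MOD_RE.match(token.strip())
        if m is None:
            raise ValidationError(f"unparsable mod token: {token!r}")
        mods.append(Mod(offset=int(m.group(2)), residue=m.group(1), state=MethylState(m.group(3))))
    return tuple(mods)


def normalize_peptide(seq: str) -> str:
    """Strip formatting characters ("*", "-", whitespace) and uppercase.

    Published peptide tables often carry bold markers around modified
    residues and line-break hyphens inside long sequences; coordinates
    refer to the clean sequence.
    """
    return re.sub(r"[\s*\-]", "", seq).upper()


@dataclass(frozen=True)
class PeptideEvidence:
    """One peptide identification with optional methyl annotations.

    Coordinates are 1-based and inclusive, with the initiator methionine
    counted; the absolute residue position of a modification is
    ``start_index + offset - 1``.  ``coords_consistent`` records whether
    the stated span matches the (normalized) sequence length and whether
    each mod's residue matches the sequence; inconsistent records are kept
    but excluded from site calling.
    """

    protein_id: str
    protein_prob: float
    peptide_seq: str
    peptide_prob: float
    start_index: int
    stop_index: int
    mods: tuple[Mod, ...] = ()
    sample_id: str = ""
    n_mod_spectra: int = 0
    n_total_spectra: int = 0
    coords_consistent: bool = field(default=True)

    def __post_init__(self) -> None:
        norm = normalize_peptide(self.peptide_seq)
        object.__setattr__(self, "peptide_seq", norm)
        if not 0.0 <= self.protein_prob <= 1.0:
            raise ValidationError("protein_prob outside [0, 1]")
        if not 0.0 <= self.peptide_prob <= 1.0:
            raise ValidationError("peptide_prob outside [0, 1]")
        if self.n_mod_spectra > self.n_total_spectra:
            raise ValidationError("n_mod_spectra exceeds n_total_spectra")
        if min(self.n_mod_spectra, self.n_total_spectra) < 0:
            raise ValidationError("negative spectrum count")
        consistent = self.stop_index - self.start_index + 1 == len(norm)
        for mod in self.mods:
            if not 1 <= mod.offset <= len(norm):
                consistent = False
            elif norm[mod.offset - 1] != mod.residue:
                consistent = False
        object.__setattr__(self, "coords_consistent", consistent)


@dataclass(frozen=True)
class ContaminantProfile:
    """Detection frequency of a protein across reference control AP-MS runs."""

    protein_id: str
    n_detected: int
    n_experiments: int
    mean_count: float = 0.0

    def __post_init__(self) -> None:
        if self.n_experiments <= 0:
            raise ValidationError("n_experiments must be positive")
        if not 0 <= self.n_detected <= self.n_experiments:
            raise ValidationError("n_detected outside [0, n_experiments]")
        if self.mean_count < 0:
            raise ValidationError("mean_count must be nonnegative")

    @property
    def frequency(self) -> float:
        return self.n_detected / self.n_experiments


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_MANIFEST_COLS = ["sample_id", "antibody", "condition", "pair_id", "run_id"]


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a sample manifest TSV.

    Expected header: sample_id, antibody, condition, pair_id, run_id.
    Blank pair_id means unpaired.  Unknown antibody/condition values and
    duplicate sample ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    if df.empty:
        raise ValidationError("no samples in manifest")
    samples = []
    for row in df.itertuples(index=False):
        try:
            ab = Antibody(row.antibody)
        except ValueError:
            raise ValidationError(f"unknown antibody: {row.antibody!r}") from None
        try:
            cond = Condition(row.condition)
        except ValueError:
            raise ValidationError(f"unknown condition: {row.condition!r}") from None
        samples.append(
            Sample(
                sample_id=row.sample_id,
                antibody=ab,
                condition=cond,
                pair_id=row.pair_id or None,
                run_id=row.run_id,
            )
        )
    return SampleManifest(tuple(samples))


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "antibody": s.antibody.value,
            "condition": s.condition.value,
            "pair_id": s.pair_id or "",
            "run_id": s.run_id,
        }
        for s in manifest.samples
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(path, sep="\t", index=False)


def read_count_matrix(
    path: str | Path, manifest: SampleManifest, count_kind: str = "total_spectra"
) -> CountMatrix:
    """Read a protein x sample count TSV and align columns to manifest order.

    The first column must be ``protein_id``; every other column name must be
    a manifest sample id.  Blank cells mean "no spectra observed" and read
    as 0; fractional or negative values are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [c for c in df.columns if c not in manifest.sample_ids]
    if unknown:
        raise ValidationError(f"sample columns absent from manifest: {unknown}")
    df = df.fillna(0)
    vals = df.to_numpy()
    if vals.size and not np.all(np.equal(np.mod(vals, 1), 0)):
        raise ValidationError("non-integer count in matrix")
    if vals.size and (vals < 0).any():
        raise ValidationError("negative count in matrix")
    ordered = [s for s in manifest.sample_ids if s in df.columns]
    df = df[ordered].astype(np.int64)
    df.index = df.index.astype(str)
    df.index.name = "protein_id"
    return CountMatrix(df=df, count_kind=count_kind)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.df.sort_index()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


_EVIDENCE_COLS = [
    "protein_id",
    "protein_prob",
    "peptide_seq",
    "peptide_prob",
    "start_index",
    "stop_index",
    "mods",
    "sample_id",
    "n_mod_spectra",
    "n_total_spectra",
]


def read_peptide_evidence(path: str | Path) -> list[PeptideEvidence]:
    """Read a peptide-evidence TSV.

    Mods are encoded ``"K4:me2;K11:me1"`` (1-based offset in peptide).
    Sequences are normalized (bold markers/hyphens stripped) before the
    coordinate-consistency check; inconsistent rows are flagged, not
    dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _EVIDENCE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"evidence table missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            mods = _parse_mods(row.mods)
        except ValidationError as exc:
            raise ValidationError(f"line {i}: {exc}") from None
        records.append(
            PeptideEvidence(
                protein_id=row.protein_id,
                protein_prob=float(row.protein_prob),
                peptide_seq=row.peptide_seq,
                peptide_prob=float(row.peptide_prob),
                start_index=int(row.start_index),
                stop_index=int(row.stop_index),
                mods=mods,
                sample_id=row.sample_id,
                n_mod_spectra=int(row.n_mod_spectra or 0),
                n_total_spectra=int(row.n_total_spectra or 0),
            )
        )
    return records


def read_contaminant_profile(path: str | Path) -> list[ContaminantProfile]:
    df = pd.read_csv(path, sep="\t")
    return [
        ContaminantProfile(
            protein_id=str(r.protein_id),
            n_detected=int(r.n_detected),
            n_experiments=int(r.n_experiments),
            mean_count=float(getattr(r, "mean_count", 0.0)),
        )
        for r in df.itertuples(index=False)
    ]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT annotation file: ``term <tab> description <tab> id...``."""
    terms: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        terms[parts[0]] = set(parts[2:])
    return terms


def read_edge_list(path: str | Path):
    """Read a weighted edge list TSV (node_a, node_b, weight) as a graph."""
    import networkx as nx

    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    for col in ("node_a", "node_b", "weight"):
        if col not in df.columns:
            raise ValidationError(f"edge list missing column {col!r}")
    g = nx.Graph()
    for r in df.itertuples(index=False):
        w = float(r.weight)
        if w <= 0:
            raise ValidationError("edge weight must be positive")
        if r.node_a == r.node_b:
            raise ValidationError(f"self-loop at {r.node_a!r} not allowed in input")
        g.add_edge(r.node_a, r.node_b, weight=w)
    return g


# ---------------------------------------------------------------------------
# generic record table round trip
# ---------------------------------------------------------------------------

# write_table/read_table serialize flat dataclasses.  Tuples of Mod and
# enum members get a text form; tuple-of-int fields (2x2 tables, count
# pairs) are serialized as "a,b,..." strings.  Sort keys per record type
# keep output deterministic.

_SORT_KEYS: dict[str, tuple[str, ...]] = {
    "PeptideEvidence": ("protein_id", "start_index", "sample_id", "peptide_seq"),
    "ContaminantProfile": ("protein_id",),
    "FoldChangeRecord": ("protein_id",),
    "ExactTestRecord": ("protein_id",),
    "EnrichmentRecord": ("protein_id",),
    "DifferentialRecord": ("protein_id",),
    "MethylSite": ("protein_id", "position", "state"),
    "CandidateTarget": ("protein_id",),
    "TermEnrichment": ("term_id",),
}


def _encode(value):
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, tuple):
        if value and isinstance(value[0], Mod):
            return ";".join(str(m) for m in value)
        return ",".join(str(_encode(v)) for v in _flatten(value))
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    return value


def _flatten(t):
    for v in t:
        if isinstance(v, tuple):
            yield from _flatten(v)
        else:
            yield v


def write_table(records: Sequence, path: str | Path, cls=None) -> None:
    """Write a homogeneous list of result records as a deterministic TSV.

    Record classes may define ``to_row()``/``from_row()`` hooks to control
    serialization of nested fields; otherwise dataclass fields are encoded
    generically.  Pass ``cls`` to get a proper header for an empty list.
    """
    if not records and cls is None:
        Path(path).write_text("protein_id\n")
        return
    cls = cls or type(records[0])
    if any(type(r) is not cls for r in records):
        raise ValidationError("write_table requires records of a single type")
    if hasattr(cls, "to_row"):
        rows = [r.to_row() for r in records]
        cols = list(rows[0]) if rows else list(cls.row_columns())
    else:
        cols = [f.name for f in fields(cls)]
        rows = [{c: _encode(getattr(r, c)) for c in cols} for r in records]
    df = pd.DataFrame(rows, columns=cols)
    keys = _SORT_KEYS.get(cls.__name__)
    if keys is not None:
        keys = [k for k in keys if k in df.columns]
    if keys:
        df = df.sort_values(list(keys), kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


#: enum classes resolvable by name during generic decoding; record modules
#: append their own members at import time.
ENUM_REGISTRY: dict[str, type] = {
    "MethylState": MethylState,
    "Antibody": Antibody,
    "Condition": Condition,
}


def _decode(text: str, ftype, fname: str):
    base = str(ftype)
    if text == "" and "None" in base:
        return None
    for name, enum_cls in ENUM_REGISTRY.items():
        if name in base:
            return enum_cls(text)
    if "Mod" in base and "tuple" in base:
        return _parse_mods(text)
    if "tuple" in base:
        nums = tuple(int(x) for x in str(text).split(",")) if str(text) != "" else ()
        if len(nums) == 4 and fname == "table":  # re-nest 2x2 tables
            return ((nums[0], nums[1]), (nums[2], nums[3]))
        return nums
    if "bool" in base:
        return str(text) == "True"
    if "int" in base:
        return int(text)
    if "float" in base:
        return float(text)
    return str(text)


def read_table(path: str | Path, cls) -> list:
    """Inverse of :func:`write_table` for a known record dataclass."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if hasattr(cls, "from_row"):
        return [cls.from_row(row._asdict()) for row in df.itertuples(index=False)]
    out = []
    for row in df.itertuples(index=False):
        kwargs = {
            f.name: _decode(getattr(row, f.name), f.type, f.name) for f in fields(cls)
        }
        out.append(cls(**kwargs))
    return out
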