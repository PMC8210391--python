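"""Reading and writing of the package's file formats.

Sequences travel as FASTA (Biopython-parsed, any line wrapping); per-protein
annotations as a TSV with tri-state boolean columns (the columns stand in for
what a UNIPROT/SignalP/TMHMM lookup would return); trained models as versioned
joblib archives.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Literal, Optional

import joblib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: ambiguous / non-canonical one-letter codes seen in curated databases
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")
#: prediction-time substitutions: selenocysteine -> Cys, pyrrolysine -> Lys
AMBIGUOUS_MAP = {"U": "C", "O": "K"}

KNOWN_LOCATIONS = ("nucleus", "cytosol", "ER", "GA", "mitochondrion", "other")

SanitizePolicy = Literal["strict", "drop_ambiguous", "map_ambiguous"]

MODEL_FORMAT_VERSION = 1


class FastaError(ValueError):
    """Malformed or unusable FASTA input."""


class AnnotationError(ValueError):
    """Malformed annotation table."""


class ModelIOError(ValueError):
    """Unreadable or incompatible persisted model."""


@dataclasses.dataclass(frozen=True)
class AnnotationEntry:
    """Tri-state per-protein annotations.

    ``None`` means unknown, which is deliberately distinct from ``False``:
    a protein may genuinely lack a signal peptide (no) or simply never have
    been run through a predictor (unknown).
    """

    is_vertebrate: Optional[bool] = None
    has_signal_peptide: Optional[bool] = None
    has_transmembrane: Optional[bool] = None
    locations: frozenset[str] = frozenset()
    uniprot_id: Optional[str] = None


#: lookup result for proteins absent from the table
ALL_UNKNOWN = AnnotationEntry()


@dataclasses.dataclass
class ProteinRecord:
    """One protein sequence with optional class label and annotations.

    label follows the secretion-predictor convention: 1 = exosome cargo
    (positive), 0 = not secreted by exosomes (negative), None = unlabeled query.
    """

    id: str
    sequence: str
    description: str = ""
    label: Optional[int] = None
    annotations: Optional[AnnotationEntry] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("protein record requires a non-empty id")
        if not self.sequence:
            raise FastaError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise FastaError(
                f"record {self.id!r}: non-canonical residue(s) {sorted(bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0/1/None")


@dataclasses.dataclass(frozen=True)
class SanitizationReport:
    """Bookkeeping of what sanitization removed or rewrote."""

    n_input: int = 0
    n_kept: int = 0
    dropped_ids: tuple[str, ...] = ()
    n_mapped_residues: int = 0
    n_removed_residues: int = 0


def sanitize_sequence(seq: str, policy: SanitizePolicy) -> tuple[str, int, int]:
    """Return (clean sequence, residues mapped, residues removed).

    strict raises on the first non-canonical residue; drop_ambiguous returns
    an empty string for any sequence containing one (caller drops the record);
    map_ambiguous rewrites U->C and O->K and deletes B/J/X/Z and anything else
    outside the canonical alphabet.
    """
    seq = seq.upper().replace("*", "").replace("-", "").replace(" ", "")
    if policy == "strict":
        for pos, ch in enumerate(seq, start=1):
            if ch not in CANONICAL_RESIDUES:
                raise FastaError(
                    f"non-canonical residue {ch!r} at position {pos}"
                )
        return seq, 0, 0
    if policy == "drop_ambiguous":
        if set(seq) - CANONICAL_RESIDUES:
            return "", 0, 0
        return seq, 0, 0
    if policy == "map_ambiguous":
        out = []
        mapped = removed = 0
        for ch in seq:
            if ch in CANONICAL_RESIDUES:
                out.append(ch)
            elif ch in AMBIGUOUS_MAP:
                out.append(AMBIGUOUS_MAP[ch])
                mapped += 1
            else:
                removed += 1
        return "".join(out), mapped, removed
    raise ValueError(f"unknown sanitize policy {policy!r}")


def read_fasta(
    path: str | Path,
    sanitize_policy: SanitizePolicy = "strict",
    label: Optional[int] = None,
    with_report: bool = False,
):
    """Parse a FASTA file into ProteinRecords.

    Returns the record list, or ``(records, SanitizationReport)`` when
    ``with_report`` is true. Raises on missing/empty files, duplicate ids and
    on files from which no record survives sanitization.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    dropped: list[str] = []
    n_input = n_mapped = n_removed = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_input += 1
        if not rec.id:
            raise FastaError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        try:
            clean, mapped, removed = sanitize_sequence(str(rec.seq), sanitize_policy)
        except FastaError as exc:
            raise FastaError(f"{path}: record {rec.id!r}: {exc}") from None
        n_mapped += mapped
        n_removed += removed
        if not clean:
            dropped.append(rec.id)
            continue
        records.append(
            ProteinRecord(id=rec.id, sequence=clean, description=rec.description, label=label)
        )
    if n_input == 0:
        raise FastaError(f"{path}: no FASTA records found")
    if not records:
        raise FastaError(f"{path}: no records survive sanitization")
    report = SanitizationReport(
        n_input=n_input,
        n_kept=len(records),
        dropped_ids=tuple(dropped),
        n_mapped_residues=n_mapped,
        n_removed_residues=n_removed,
    )
    return (records, report) if with_report else records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as wrapped FASTA (default 60 columns)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    path = Path(path)
    with path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


_BOOL_TOKENS = {
    "yes": True, "y": True, "true": True, "1": True,
    "no": False, "n": False, "false": False, "0": False,
    "unknown": None, "na": None, "?": None, "": None, "nan": None,
}

_ANNOTATION_COLUMNS = (
    "id", "is_vertebrate", "has_signal_peptide", "has_transmembrane",
    "locations", "uniprot_id",
)


class AnnotationTable(dict):
    """id -> AnnotationEntry mapping; unknown ids resolve to all-unknown."""

    def __missing__(self, key: str) -> AnnotationEntry:
        return ALL_UNKNOWN

    def get(self, key, default=ALL_UNKNOWN):  # noqa: D102 - dict override
        return super().get(key, default)


def _parse_bool(token: str, row: int, column: str) -> Optional[bool]:
    token = token.strip().lower()
    if token not in _BOOL_TOKENS:
        raise AnnotationError(
            f"row {row}: column {column!r}: cannot interpret {token!r} as yes/no/unknown"
        )
    return _BOOL_TOKENS[token]


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read the tab-separated annotation table.

    Expected header: id, is_vertebrate, has_signal_peptide, has_transmembrane,
    locations (semicolon-separated), uniprot_id. Trailing columns beyond
    ``locations`` may be omitted per-row.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation table not found: {path}")
    table = AnnotationTable()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip() for h in header[: len(_ANNOTATION_COLUMNS)]] != list(
            _ANNOTATION_COLUMNS[: len(header)]
        ):
            raise AnnotationError(
                f"{path}: expected header columns {_ANNOTATION_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationError(f"{path}: row {lineno}: too few columns")
            fields += [""] * (len(_ANNOTATION_COLUMNS) - len(fields))
            rec_id = fields[0].strip()
            if not rec_id:
                raise AnnotationError(f"{path}: row {lineno}: empty id")
            if rec_id in table:
                raise AnnotationError(f"{path}: row {lineno}: duplicate id {rec_id!r}")
            locations = frozenset(
                tok.strip() for tok in fields[4].split(";") if tok.strip()
            )
            uniprot = fields[5].strip() or None
            table[rec_id] = AnnotationEntry(
                is_vertebrate=_parse_bool(fields[1], lineno, "is_vertebrate"),
                has_signal_peptide=_parse_bool(fields[2], lineno, "has_signal_peptide"),
                has_transmembrane=_parse_bool(fields[3], lineno, "has_transmembrane"),
                locations=locations,
                uniprot_id=uniprot,
            )
    return table


def _bool_token(value: Optional[bool]) -> str:
    return {True: "yes", False: "no", None: "unknown"}[value]


def write_annotations(table: dict[str, AnnotationEntry], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
        for rec_id in sorted(table):
            e = table[rec_id]
            fh.write(
                "\t".join(
                    [
                        rec_id,
                        _bool_token(e.is_vertebrate),
                        _bool_token(e.has_signal_peptide),
                        _bool_token(e.has_transmembrane),
                        ";".join(sorted(e.locations)),
                        e.uniprot_id or "",
                    ]
                )
                + "\n"
            )


@dataclasses.dataclass(frozen=True)
class DatasetManifest:
    """Paths of one labeled training dataset (JSON on disk)."""

    name: str
    positives_path: Path
    negatives_path: Path
    annotation_path: Optional[Path] = None


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    data = json.loads(path.read_text())
    base = path.parent

    def resolve(key: str, required: bool) -> Optional[Path]:
        raw = data.get(key)
        if raw is None:
            if required:
                raise ValueError(f"manifest {path}: missing {key!r}")
            return None
        p = (base / raw).resolve() if not Path(raw).is_absolute() else Path(raw)
        if not p.exists():
            raise FileNotFoundError(f"manifest {path}: {key} -> {p} does not exist")
        return p

    return DatasetManifest(
        name=str(data.get("name", path.stem)),
        positives_path=resolve("positives_path", required=True),
        negatives_path=resolve("negatives_path", required=True),
        annotation_path=resolve("annotation_path", required=False),
    )


def load_dataset(
    manifest: DatasetManifest, sanitize_policy: SanitizePolicy = "drop_ambiguous"
) -> tuple[list[ProteinRecord], AnnotationTable]:
    """Load labeled records (positives then negatives) plus annotations."""
    positives = read_fasta(manifest.positives_path, sanitize_policy, label=1)
    negatives = read_fasta(manifest.negatives_path, sanitize_policy, label=0)
    ids = [r.id for r in positives] + [r.id for r in negatives]
    if len(set(ids)) != len(ids):
        raise FastaError(f"dataset {manifest.name!r}: ids shared between classes")
    annotations = (
        read_annotations(manifest.annotation_path)
        if manifest.annotation_path
        else AnnotationTable()
    )
    return positives + negatives, annotations


def save_model(bundle, path: str | Path) -> None:
    """Persist a trained ModelBundle as a versioned joblib archive."""
    payload = {"format_version": MODEL_FORMAT_VERSION, "bundle": bundle}
    joblib.dump(payload, path)


def load_model(path: str | Path):
    """Load a ModelBundle saved by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"model file not found: {path}")
    try:
        payload = joblib.load(path)
    except Exception as exc:  # joblib raises a zoo of unpickling errors
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelIOError(f"{path}: not an exopred model archive")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"{path}: model format version {payload['format_version']} "
            f"not supported (library supports {MODEL_FORMAT_VERSION})"
        )
    return payload["bundle"]
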