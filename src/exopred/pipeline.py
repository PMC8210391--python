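"""Dataset curation and the gated prediction report.

The predictor is only meaningful for vertebrate proteins that reach the
extracellular space without the classical route: queries flagged as
non-vertebrate, signal-peptide-bearing, or transmembrane are not scored and
receive NA. The same three filters, plus per-class redundancy reduction,
build the training datasets.

Unknown annotations are handled asymmetrically: dataset building drops them
(training purity), prediction scores them (a query without a database hit
still deserves an answer), with the asymmetry behind explicit flags.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import pandas as pd

from .io_formats import (
    ALL_UNKNOWN,
    AnnotationEntry,
    AnnotationTable,
    ProteinRecord,
)
from .modeling import ModelBundle, ModelingError, predict_scores
from .similarity import reduce_redundancy

KNOWN_LOCATIONS = ("nucleus", "cytosol", "ER", "GA", "mitochondrion", "other")


class PipelineError(ValueError):
    pass


@dataclasses.dataclass
class CurationLog:
    """Per-step removal counts; steps never increase the record count."""

    n_input: int = 0
    removed_non_vertebrate: int = 0
    removed_signal_peptide: int = 0
    removed_transmembrane: int = 0
    removed_unknown_annotation: int = 0
    removed_redundant: int = 0
    n_output: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def total_removed(self) -> int:
        return (
            self.removed_non_vertebrate
            + self.removed_signal_peptide
            + self.removed_transmembrane
            + self.removed_unknown_annotation
            + self.removed_redundant
        )


def curate_dataset(
    records: Sequence[ProteinRecord],
    annotations: AnnotationTable,
    identity_threshold: float = 80.0,
    drop_unknown: bool = True,
) -> tuple[list[ProteinRecord], dict[int, CurationLog]]:
    """Apply the training-dataset filter chain, per class label.

    Order: drop non-vertebrate, drop signal-peptide carriers, drop
    transmembrane proteins, then reduce redundancy within each class so no
    retained pair exceeds the identity threshold. With ``drop_unknown``
    (the dataset-building default), records whose filter fields are unknown
    are removed and counted separately.

    Returns the curated records and one CurationLog per class label.
    """
    if not records:
        raise PipelineError("no records to curate")
    logs: dict[int, CurationLog] = {}
    curated: list[ProteinRecord] = []
    labels = sorted({r.label for r in records}, key=lambda x: (x is None, x))
    for label in labels:
        group = [r for r in records if r.label == label]
        log = CurationLog(n_input=len(group))

        def known_pass(flag: Optional[bool], want: bool) -> Optional[bool]:
            """None = unknown; True/False = keep/remove decision."""
            if flag is None:
                return None
            return flag is want

        survivors = []
        for rec in group:
            entry = annotations.get(rec.id, ALL_UNKNOWN)
            checks = (
                ("removed_non_vertebrate", known_pass(entry.is_vertebrate, True)),
                ("removed_signal_peptide", known_pass(entry.has_signal_peptide, False)),
                ("removed_transmembrane", known_pass(entry.has_transmembrane, False)),
            )
            fate = None
            for counter, verdict in checks:
                if verdict is False:
                    fate = counter
                    break
                if verdict is None and drop_unknown:
                    fate = "removed_unknown_annotation"
                    break
            if fate is None:
                survivors.append(rec)
            else:
                setattr(log, fate, getattr(log, fate) + 1)
        if not survivors:
            raise PipelineError(
                f"class {label!r}: no records survive annotation filters"
            )
        retained, cluster_map = reduce_redundancy(survivors, identity_threshold)
        log.removed_redundant = len(cluster_map)
        log.n_output = len(retained)
        logs[label] = log
        curated.extend(retained)
    return curated, logs


def write_curation_log(logs: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump({str(k): v.as_dict() for k, v in logs.items()}, fh, indent=2)


PREDICTION_COLUMNS = (
    "index",
    "sequence_name",
    "is_vertebrate",
    "uniprot_id",
    "signal_peptide",
    "transmembrane",
    "location_annotated",
    "exosome_secretion",
    "score",
)


@dataclasses.dataclass(frozen=True)
class PredictionRow:
    index: int
    sequence_name: str
    is_vertebrate: str  # Y / N / unknown
    uniprot_id: str  # id or "not found"
    signal_peptide: str  # Y / N
    transmembrane: str  # Y / N
    location_annotated: str  # semicolon-joined or "not found"
    exosome_secretion: str  # Y / N / NA
    score: Optional[float]


def _yn(flag: Optional[bool], unknown_as: str) -> str:
    if flag is None:
        return unknown_as
    return "Y" if flag else "N"


def gate_and_predict(
    records: Sequence[ProteinRecord],
    annotations: AnnotationTable,
    bundle: ModelBundle,
    unknown_sp_tm_as_no: bool = True,
) -> list[PredictionRow]:
    """Score queries through the NA gate.

    A record is scored only if it is not known to be non-vertebrate and has
    no signal peptide or transmembrane region; otherwise the secretion call
    is NA and no score is produced. Unknown vertebrate status does not block
    scoring (queries without a database equivalent are still answered, the
    taxon column showing "unknown"). Unknown SP/TM status is treated as "no"
    when ``unknown_sp_tm_as_no`` is set (the prediction-time default),
    otherwise those records are gated to NA as well.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ModelingError("duplicate record ids in prediction batch")
    entries = [annotations.get(r.id, ALL_UNKNOWN) for r in records]

    def resolved(flag: Optional[bool]) -> Optional[bool]:
        if flag is None and unknown_sp_tm_as_no:
            return False
        return flag

    gated_out = []
    for entry in entries:
        sp = resolved(entry.has_signal_peptide)
        tm = resolved(entry.has_transmembrane)
        blocked = (
            entry.is_vertebrate is False
            or sp is not False
            or tm is not False
        )
        gated_out.append(blocked)

    scorable = [r for r, blocked in zip(records, gated_out) if not blocked]
    scores = (
        predict_scores(bundle, scorable) if scorable else pd.DataFrame(columns=["score", "call"])
    )

    rows: list[PredictionRow] = []
    for i, (rec, entry, blocked) in enumerate(zip(records, entries, gated_out), start=1):
        sp = resolved(entry.has_signal_peptide)
        tm = resolved(entry.has_transmembrane)
        if blocked:
            call, score = "NA", None
        else:
            call = str(scores.loc[rec.id, "call"])
            score = float(scores.loc[rec.id, "score"])
        rows.append(
            PredictionRow(
                index=i,
                sequence_name=rec.id,
                is_vertebrate=_yn(entry.is_vertebrate, "unknown"),
                uniprot_id=entry.uniprot_id or "not found",
                signal_peptide=_yn(sp, "unknown"),
                transmembrane=_yn(tm, "unknown"),
                location_annotated=";".join(sorted(entry.locations)) or "not found",
                exosome_secretion=call,
                score=score,
            )
        )
    return rows


def prediction_table(rows: Sequence[PredictionRow]) -> pd.DataFrame:
    """Fixed-column report frame (left-to-right as the web report prints)."""
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in rows], columns=list(PREDICTION_COLUMNS)
    )


@dataclasses.dataclass(frozen=True)
class LocationTally:
    exclusive: dict[str, int]
    multi_location: int
    unannotated: int
    n_records: int


def location_tally(
    records: Sequence[ProteinRecord], annotations: AnnotationTable
) -> LocationTally:
    """Count proteins by exclusive sub-cellular location.

    A protein counts toward location L only if L is its sole annotated
    location; proteins with several locations and proteins with none are
    tallied separately, so the three groups partition the input.
    """
    exclusive = {loc: 0 for loc in KNOWN_LOCATIONS}
    multi = unannotated = 0
    for rec in records:
        locs = annotations.get(rec.id, ALL_UNKNOWN).locations
        if not locs:
            unannotated += 1
        elif len(locs) > 1:
            multi += 1
        else:
            (only,) = locs
            exclusive[only] = exclusive.get(only, 0) + 1
    return LocationTally(
        exclusive=exclusive,
        multi_location=multi,
        unannotated=unannotated,
        n_records=len(records),
    )
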