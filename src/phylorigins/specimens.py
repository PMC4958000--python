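"""Specimen metadata: which louse samples yielded putative endosymbiont 16S
sequences, and AT-content screening of those sequences.

A packaged table of 23 Anoplura specimens (8 families, 21 species) ships with
the module so that the screening summaries are computable offline.  AT
percentages are stored at the integer precision they are conventionally
reported at; one specimen can carry several endosymbiont sequences, hence the
``at_percents`` list.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

from phylorigins.errors import ValidationError


@dataclass(frozen=True)
class SpecimenRecord:
    louse_species: str
    taxon_label: str
    endosymbiont_present: bool
    at_percents: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.endosymbiont_present != (len(self.at_percents) > 0):
            raise ValidationError(
                f"{self.taxon_label}: endosymbiont_present must match the "
                "presence of AT-content entries"
            )
        if any(not (0.0 <= p <= 100.0) for p in self.at_percents):
            raise ValidationError(f"{self.taxon_label}: AT percent outside [0, 100]")

    @property
    def n_endo_sequences(self) -> int:
        return len(self.at_percents)


class SpecimenSummary(NamedTuple):
    n_specimens: int
    n_specimens_with_endosymbiont: int
    n_endo_sequences_total: int
    n_endo_sequences_at_or_above: int


def read_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    """Read a specimen TSV with columns
    ``species  taxon_label  endosymbiont_present  at_percents``
    where ``at_percents`` is comma-separated and empty for negatives."""
    records = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            raw = (row.get("at_percents") or "").strip()
            percents = tuple(float(p) for p in raw.split(",")) if raw else ()
            records.append(
                SpecimenRecord(
                    louse_species=row["species"],
                    taxon_label=row["taxon_label"],
                    endosymbiont_present=row["endosymbiont_present"].strip().lower()
                    in {"yes", "true", "1"},
                    at_percents=percents,
                )
            )
    if not records:
        raise ValidationError(f"no specimen rows in {path}")
    return records


def load_anoplura_specimens() -> list[SpecimenRecord]:
    """The packaged 23-specimen sucking-louse screening table."""
    ref = resources.files("phylorigins").joinpath("data/anoplura_specimens.tsv")
    with resources.as_file(ref) as path:
        return read_specimen_table(path)


def summarize_specimens(
    records: Sequence[SpecimenRecord], at_threshold: float = 50.0
) -> SpecimenSummary:
    """Screening summary: specimen and sequence counts, and how many
    endosymbiont sequences have AT content at or above ``at_threshold``."""
    if not records:
        raise ValidationError("no specimen records")
    if not (0.0 <= at_threshold <= 100.0):
        raise ValidationError("AT threshold must be in [0, 100]")
    n_with = sum(1 for r in records if r.endosymbiont_present)
    n_seqs = sum(r.n_endo_sequences for r in records)
    n_at = sum(
        1 for r in records for p in r.at_percents if p >= at_threshold
    )
    return SpecimenSummary(len(records), n_with, n_seqs, n_at)
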