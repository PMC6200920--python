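"""Curated RFamide peptide and precursor catalog.

The packaged catalog holds 97 mature amidated peptides: 26 chordate
GnIH-family (LPXRFamide/PQRFamide) peptides from eight species and 71
distinct FMRFamide-like peptides (FLPs) encoded by the 31 *flp* genes of
*C. elegans* (41 of them biochemically identified).  Sequences are stored
as plain amino-acid strings; the C-terminal amide is a boolean flag and is
rendered as a trailing lowercase "a" only at display time, so distance
computations always operate on pure residue strings.

A separate precursor manifest lists the 51 precursor polypeptides (by
accession, sequences not included) used for precursor-level phylogenetics,
including the single hydra insulin-like peptide 2 outgroup.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CatalogError",
    "PeptideRecord",
    "PrecursorRecord",
    "CatalogSummary",
    "load_peptides",
    "load_precursors",
    "load_catalog",
    "summarize_catalog",
    "write_peptides_tsv",
    "peptides_to_fasta",
    "display_sequence",
]

VALID_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_SEQ_RE = re.compile(rf"^[{VALID_RESIDUES}]+$")

#: the five C-terminal groups, in the catalog's reporting order
GROUP_NAMES = ("MRFa", "LRFa", "VRFa", "PQRFa", "IRFa")

PEPTIDE_COLUMNS = (
    "peptide_id",
    "sequence",
    "amidated",
    "identified",
    "copy_number",
    "gene_id",
    "species",
    "clade_label",
    "reference_group",
)

PRECURSOR_COLUMNS = ("precursor_id", "species", "family", "accession")

#: *flp* genes absent from C. elegans (orthologous or specific to parasitic
#: nematodes); recorded as absent genes, not zero-peptide genes.
ABSENT_FLP_GENES = ("flp-29", "flp-30", "flp-31")


class CatalogError(ValueError):
    """Raised when a catalog file or record fails validation."""


@dataclass(frozen=True)
class PeptideRecord:
    """One mature (or predicted) amidated peptide.

    ``sequence`` is the peptide body without the amide marker;
    ``copy_number`` is the number of copies encoded in the parent precursor
    (distinct-peptide counts ignore it); ``reference_group`` is the curated
    five-group assignment where available.
    """

    peptide_id: str
    sequence: str
    amidated: bool = True
    identified: bool = False
    copy_number: int = 1
    gene_id: str = ""
    species: str = ""
    clade_label: str = ""
    reference_group: str | None = None

    def __post_init__(self) -> None:
        if not _SEQ_RE.match(self.sequence):
            bad = next(
                (c for c in self.sequence if c not in VALID_RESIDUES), "?"
            )
            raise CatalogError(
                f"peptide {self.peptide_id!r}: illegal residue {bad!r} "
                f"in sequence {self.sequence!r}"
            )
        if len(self.sequence) < 4:
            raise CatalogError(
                f"peptide {self.peptide_id!r}: sequence shorter than 4 residues"
            )
        if self.copy_number < 1:
            raise CatalogError(
                f"peptide {self.peptide_id!r}: copy_number must be positive"
            )
        if self.reference_group is not None and not self.amidated:
            raise CatalogError(
                f"peptide {self.peptide_id!r}: grouped peptides must be amidated"
            )
        if self.reference_group is not None and self.reference_group not in GROUP_NAMES:
            raise CatalogError(
                f"peptide {self.peptide_id!r}: unknown group "
                f"{self.reference_group!r}"
            )


@dataclass(frozen=True)
class PrecursorRecord:
    """A precursor polypeptide referenced by accession.

    Sequences are not distributed; users may attach one (e.g. from a FASTA
    they supply) via :func:`dataclasses.replace`.
    """

    precursor_id: str
    species: str
    family: str
    accession: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise CatalogError(
                f"precursor {self.precursor_id!r}: empty accession"
            )
        if self.family not in ("GnIH", "NPFF", "FLP", "FMRFamide", "outgroup"):
            raise CatalogError(
                f"precursor {self.precursor_id!r}: unknown family "
                f"{self.family!r}"
            )
        if self.sequence is not None and not _SEQ_RE.match(self.sequence):
            raise CatalogError(
                f"precursor {self.precursor_id!r}: invalid sequence"
            )


@dataclass(frozen=True)
class CatalogSummary:
    n_flp_genes: int
    n_flps_total: int
    n_flps_identified: int
    max_flps_per_gene: int
    n_chordate_peptides: int
    n_peptides_total: int


def display_sequence(record: PeptideRecord) -> str:
    """Render a peptide the way the field prints it, e.g. ``KSAYMRFa``."""
    return record.sequence + ("a" if record.amidated else "")


def _data_path(name: str):
    return resources.files("rfamide.data").joinpath(name)


def _parse_bool(value: str, where: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise CatalogError(f"{where}: cannot parse boolean {value!r}")


def _read_peptide_rows(handle, source: str) -> list[PeptideRecord]:
    reader = csv.DictReader(handle, delimiter="\t")
    missing = set(PEPTIDE_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise CatalogError(
            f"{source}: missing columns {sorted(missing)}"
        )
    records = []
    for row in reader:
        group = (row.get("reference_group") or "").strip() or None
        records.append(
            PeptideRecord(
                peptide_id=row["peptide_id"].strip(),
                sequence=row["sequence"].strip(),
                amidated=_parse_bool(row["amidated"], row["peptide_id"]),
                identified=_parse_bool(row["identified"], row["peptide_id"]),
                copy_number=int(row["copy_number"]),
                gene_id=row["gene_id"].strip(),
                species=row["species"].strip(),
                clade_label=row["clade_label"].strip(),
                reference_group=group,
            )
        )
    ids = [r.peptide_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise CatalogError(f"{source}: duplicate peptide_id {sorted(dupes)}")
    return records


def load_peptides(
    source: str | Path | None = None,
    include_predicted_extras: bool = False,
) -> list[PeptideRecord]:
    """Load peptide records from the packaged catalog or a user TSV.

    The default catalog contains exactly the 97 grouped peptides.  With
    ``include_predicted_extras`` the predicted-but-ungrouped quail RSamide
    peptide (APNLSNRSa) is appended; it carries no ``reference_group`` so
    the grouped set stays exact.
    """
    if source is None:
        with _data_path("peptides.tsv").open("r", encoding="utf-8") as fh:
            records = _read_peptide_rows(fh, "packaged catalog")
        if include_predicted_extras:
            with _data_path("peptides_predicted_extra.tsv").open(
                "r", encoding="utf-8"
            ) as fh:
                records += _read_peptide_rows(fh, "predicted extras")
        return records
    with open(source, "r", encoding="utf-8") as fh:
        return _read_peptide_rows(fh, str(source))


def load_precursors(source: str | Path | None = None) -> list[PrecursorRecord]:
    """Load the precursor manifest (packaged by default; 51 records)."""
    if source is None:
        handle = _data_path("precursors.tsv").open("r", encoding="utf-8")
        name = "packaged manifest"
    else:
        handle = open(source, "r", encoding="utf-8")
        name = str(source)
    with handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(PRECURSOR_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise CatalogError(f"{name}: missing columns {sorted(missing)}")
        records = [
            PrecursorRecord(
                precursor_id=row["precursor_id"].strip(),
                species=row["species"].strip(),
                family=row["family"].strip(),
                accession=row["accession"].strip(),
            )
            for row in reader
        ]
    accs = [r.accession for r in records]
    dupes = {a for a in accs if accs.count(a) > 1}
    if dupes:
        raise CatalogError(f"{name}: duplicate accessions {sorted(dupes)}")
    return records


def load_catalog(
    peptide_source: str | Path | None = None,
    precursor_source: str | Path | None = None,
    include_predicted_extras: bool = False,
) -> tuple[list[PeptideRecord], list[PrecursorRecord]]:
    """Load peptides and precursor manifest together."""
    return (
        load_peptides(peptide_source, include_predicted_extras),
        load_precursors(precursor_source),
    )


def summarize_catalog(records: Sequence[PeptideRecord]) -> CatalogSummary:
    """Count distinct peptides, genes and identifications.

    Copy numbers never multiply distinct-peptide counts: the FLP total of
    71 counts distinct sequences, so e.g. FLP-6 (encoded six times in its
    precursor) counts once.
    """
    if not records:
        raise CatalogError("empty catalog")
    flps = [r for r in records if r.clade_label == "nematode"]
    chordates = [r for r in records if r.clade_label == "chordate"]
    genes: dict[str, int] = {}
    for r in flps:
        genes[r.gene_id] = genes.get(r.gene_id, 0) + 1
    return CatalogSummary(
        n_flp_genes=len(genes),
        n_flps_total=len(flps),
        n_flps_identified=sum(r.identified for r in flps),
        max_flps_per_gene=max(genes.values(), default=0),
        n_chordate_peptides=len(chordates),
        n_peptides_total=len(records),
    )


def write_peptides_tsv(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records in the catalog TSV schema (round-trips losslessly)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PEPTIDE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.peptide_id,
                    r.sequence,
                    "true" if r.amidated else "false",
                    "true" if r.identified else "false",
                    r.copy_number,
                    r.gene_id,
                    r.species,
                    r.clade_label,
                    r.reference_group or "",
                ]
            )


def peptides_to_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Export peptides as protein FASTA (id = peptide_id, description =
    gene + species)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=r.peptide_id.replace(" ", "_"),
            description=f"{r.gene_id} | {r.species}",
        )
        for r in records
    ]
    seqio_write(seqs, str(path), "fasta")


def records_equal(a: Sequence[PeptideRecord], b: Sequence[PeptideRecord]) -> bool:
    """Field-by-field equality of two record collections."""
    if len(a) != len(b):
        return False
    return all(
        all(getattr(x, f.name) == getattr(y, f.name) for f in fields(PeptideRecord))
        for x, y in zip(a, b)
    )
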