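"""Prohormone processing: cleavage-site and mature-peptide prediction.

Mature RFamide peptides sit inside their precursor polypeptide flanked by an
amidation-signal glycine plus one or two basic residues (K/R, the
endoproteolytic site) at the C-terminal end, and a mono- or dibasic K/R site
upstream.  During processing the convertases cut at the basic residues, a
carboxypeptidase trims them, and the exposed glycine donates the C-terminal
amide.  This module predicts those peptides directly from sequence:

* :func:`find_amidation_sites` reports every ``G`` immediately followed by
  one or two K/R residues;
* :func:`predict_peptides` derives the peptide body for each site and
  annotates its C-terminal motif;
* :func:`annotate_motif` labels a sequence by its C-terminus
  (``LPXRFa-L``/``LPXRFa-Q`` for the jawed-vertebrate GnIH motifs,
  ``PQRFa``, ``generic-RFa``, or ``non-RFa-amide``).

Coordinates are 0-based half-open; the amidation glycine and the basic run
are not part of the peptide body.

The upstream boundary is the nearest upstream K/R that leaves a body at
least ``min_len`` residues long.  Nearly every RFamide peptide carries an
arginine two residues before the glycine (the R of the R-F-amide terminus),
so a literal nearest-basic rule would truncate essentially every true
peptide to a single residue; skipping basics that leave an implausibly
short body restores the intended cut.  If no basic residue yields a valid
body the nearest one is still used (the call then falls to the length
filter), and with no upstream basic at all the body starts at position 0
and the call is flagged ``n_terminal_open``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .catalog import VALID_RESIDUES, PrecursorRecord

__all__ = [
    "ProcessingError",
    "ProcessingParams",
    "CleavageSite",
    "MaturePeptideCall",
    "find_amidation_sites",
    "predict_peptides",
    "predict_from_sequence",
    "annotate_motif",
    "MOTIFS",
]

_BASIC = frozenset("KR")

#: motif labels, most to least specific
MOTIFS = ("LPXRFa-L", "LPXRFa-Q", "PQRFa", "generic-RFa", "non-RFa-amide")


class ProcessingError(ValueError):
    """Raised for invalid sequences or parameters."""


@dataclass(frozen=True)
class ProcessingParams:
    """Tunable prediction parameters.

    ``min_len``/``max_len`` bound the peptide body (defaults 4 and 40
    bracket all cataloged peptides, from AMMRFa to the 24-residue FLP-33);
    ``require_rf_family`` drops calls whose motif is ``non-RFa-amide``.
    """

    min_len: int = 4
    max_len: int = 40
    require_rf_family: bool = False

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ProcessingError("min_len must be >= 1")
        if self.min_len > self.max_len:
            raise ProcessingError("min_len may not exceed max_len")


@dataclass(frozen=True)
class CleavageSite:
    """An amidation cassette: glycine position plus trailing basic run."""

    position: int
    basic_run: str
    kind: str  # amidation-monobasic | amidation-dibasic


@dataclass(frozen=True)
class MaturePeptideCall:
    precursor_id: str
    start: int
    end: int
    sequence: str
    motif: str
    cleavage: CleavageSite
    n_terminal_open: bool = False
    amidated: bool = True


def _validate(sequence: str) -> None:
    if not sequence:
        raise ProcessingError("empty sequence")
    for i, c in enumerate(sequence):
        if c not in VALID_RESIDUES:
            raise ProcessingError(
                f"illegal residue {c!r} at position {i}"
            )


def find_amidation_sites(sequence: str) -> list[CleavageSite]:
    """Scan left to right for every G followed by one or two K/R residues.

    A glycine followed by two basics (GKR, GRR, GRK, GKK) reports a dibasic
    run; a single trailing basic reports a monobasic run.
    """
    _validate(sequence)
    sites = []
    for pos, residue in enumerate(sequence):
        if residue != "G":
            continue
        run = sequence[pos + 1 : pos + 3]
        run = run[: _basic_run_length(run)]
        if run:
            kind = "amidation-dibasic" if len(run) == 2 else "amidation-monobasic"
            sites.append(CleavageSite(position=pos, basic_run=run, kind=kind))
    return sites


def _basic_run_length(following: str) -> int:
    n = 0
    for c in following:
        if c in _BASIC:
            n += 1
        else:
            break
    return n


def annotate_motif(sequence: str) -> str:
    """Label a peptide body by its C-terminal motif."""
    _validate(sequence)
    if sequence.endswith("LPLRF"):
        return "LPXRFa-L"
    if sequence.endswith("LPQRF"):
        return "LPXRFa-Q"
    if sequence.endswith("PQRF"):
        return "PQRFa"
    if sequence.endswith("RF"):
        return "generic-RFa"
    return "non-RFa-amide"


def _body_start(sequence: str, glycine: int, min_len: int) -> tuple[int, bool]:
    """Return (start, n_terminal_open) for the peptide ending at ``glycine``."""
    nearest_basic = None
    for q in range(glycine - 1, -1, -1):
        if sequence[q] in _BASIC:
            if nearest_basic is None:
                nearest_basic = q
            if glycine - q - 1 >= min_len:
                return q + 1, False
    if nearest_basic is None:
        return 0, True
    return nearest_basic + 1, False


def predict_peptides(
    precursor: PrecursorRecord,
    params: ProcessingParams | None = None,
) -> list[MaturePeptideCall]:
    """Predict mature amidated peptides on a precursor with a sequence."""
    if precursor.sequence is None:
        raise ProcessingError(
            f"precursor {precursor.precursor_id!r} has no sequence; supply "
            "one via FASTA (the catalog ships accessions only)"
        )
    return predict_from_sequence(
        precursor.precursor_id, precursor.sequence, params
    )


def predict_from_sequence(
    precursor_id: str,
    sequence: str,
    params: ProcessingParams | None = None,
) -> list[MaturePeptideCall]:
    """Predict mature amidated peptides from a raw precursor sequence."""
    params = params or ProcessingParams()
    calls = []
    for site in find_amidation_sites(sequence):
        start, open_end = _body_start(sequence, site.position, params.min_len)
        body = sequence[start : site.position]
        if not params.min_len <= len(body) <= params.max_len:
            continue
        motif = annotate_motif(body)
        if params.require_rf_family and motif == "non-RFa-amide":
            continue
        calls.append(
            MaturePeptideCall(
                precursor_id=precursor_id,
                start=start,
                end=site.position,
                sequence=body,
                motif=motif,
                cleavage=site,
                n_terminal_open=open_end,
            )
        )
    calls.sort(key=lambda c: (c.start, c.end))
    return calls


def calls_to_rows(calls: Sequence[MaturePeptideCall]) -> list[dict]:
    """Flatten calls for TSV output."""
    return [
        {
            "precursor_id": c.precursor_id,
            "start": c.start,
            "end": c.end,
            "sequence": c.sequence,
            "motif": c.motif,
            "cleavage_kind": c.cleavage.kind,
            "n_terminal_open": c.n_terminal_open,
        }
        for c in calls
    ]
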