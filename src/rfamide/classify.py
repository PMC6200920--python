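"""Five-group C-terminal classification of RFamide peptides.

Chordate GnIH-family peptides and *C. elegans* FLPs partition into five
groups named for their last C-terminal residues: MRFa, LRFa, VRFa, PQRFa
and IRFa.  Classification is a pure function of the sequence plus a small
exception table, decided in this order:

1. exact-sequence exceptions (default: the single entry FLP-33, whose
   terminal ...KPRFa matches no -3 residue class but which groups with the
   LRFa peptides);
2. a ``PQRF`` suffix -> PQRFa (amide implied);
3. the "-3 rule": residue -2 is R, residue -1 is one of F/Y/S/L, and the
   residue at -3 (M, L, V or I) names the group;
4. otherwise UNRESOLVED.

The -1 tolerance set {F, Y, S, L} is the minimal set covering the
catalog's non-F amides (FLP-1-8 ...MRYa, human RFRP-2 ...LRSa, coelacanth
LPXRFa-2 ...LRLa); widening it changes nothing on the packaged catalog.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .catalog import GROUP_NAMES, CatalogError, PeptideRecord, VALID_RESIDUES

__all__ = [
    "GroupAssignment",
    "ClassificationResult",
    "DEFAULT_EXCEPTIONS",
    "classify_peptide",
    "classify_set",
    "load_exceptions_tsv",
]

#: peptides grouped by curated placement rather than their own C-terminus
DEFAULT_EXCEPTIONS: Mapping[str, str] = {
    "APLEGFEDMSGFLRTIDGIQKPRF": "LRFa",  # FLP-33
}

_MINUS3 = {"M": "MRFa", "L": "LRFa", "V": "VRFa", "I": "IRFa"}
_MINUS1_TOLERATED = frozenset("FYSL")


@dataclass(frozen=True)
class GroupAssignment:
    group: str  # one of GROUP_NAMES or "UNRESOLVED"
    rule_path: str  # pqrf-suffix | minus3-rule | exception-table | unresolved
    peptide_id: str | None = None


@dataclass(frozen=True)
class ClassificationResult:
    """Grouping table plus per-group membership and concordance."""

    table: pd.DataFrame  # peptide_id, sequence, group, rule_path,
    #                      ground_truth_group, concordant
    group_sizes: dict[str, int]
    members: dict[str, list[str]]  # group -> peptide_ids sorted
    n_concordant: int
    n_with_ground_truth: int

    @property
    def fully_concordant(self) -> bool:
        return self.n_concordant == self.n_with_ground_truth


def classify_peptide(
    sequence: str,
    exceptions: Mapping[str, str] | None = None,
) -> GroupAssignment:
    """Assign one peptide body (amide implied) to a C-terminal group."""
    if len(sequence) < 3:
        raise CatalogError("sequence shorter than 3 residues")
    for i, c in enumerate(sequence):
        if c not in VALID_RESIDUES:
            raise CatalogError(f"illegal residue {c!r} at position {i}")
    exceptions = DEFAULT_EXCEPTIONS if exceptions is None else exceptions
    if sequence in exceptions:
        return GroupAssignment(exceptions[sequence], "exception-table")
    if sequence.endswith("PQRF"):
        return GroupAssignment("PQRFa", "pqrf-suffix")
    if sequence[-2] == "R" and sequence[-1] in _MINUS1_TOLERATED:
        group = _MINUS3.get(sequence[-3])
        if group is not None:
            return GroupAssignment(group, "minus3-rule")
    return GroupAssignment("UNRESOLVED", "unresolved")


def classify_set(
    records: Sequence[PeptideRecord],
    exceptions: Mapping[str, str] | None = None,
) -> ClassificationResult:
    """Classify a peptide collection and report concordance with the
    curated reference groups where present."""
    rows = []
    for r in records:
        a = classify_peptide(r.sequence, exceptions)
        rows.append(
            {
                "peptide_id": r.peptide_id,
                "sequence": r.sequence,
                "group": a.group,
                "rule_path": a.rule_path,
                "ground_truth_group": r.reference_group,
                "concordant": (
                    a.group == r.reference_group
                    if r.reference_group is not None
                    else None
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "peptide_id",
            "sequence",
            "group",
            "rule_path",
            "ground_truth_group",
            "concordant",
        ],
    )
    sizes = {g: 0 for g in GROUP_NAMES}
    members: dict[str, list[str]] = {g: [] for g in GROUP_NAMES}
    for row in rows:
        g = row["group"]
        sizes[g] = sizes.get(g, 0) + 1
        members.setdefault(g, []).append(row["peptide_id"])
    for ids in members.values():
        ids.sort()
    with_truth = [r for r in rows if r["concordant"] is not None]
    return ClassificationResult(
        table=table,
        group_sizes=sizes,
        members=members,
        n_concordant=sum(bool(r["concordant"]) for r in with_truth),
        n_with_ground_truth=len(with_truth),
    )


def load_exceptions_tsv(path: str | Path) -> dict[str, str]:
    """Read a user exception table: columns ``sequence`` and ``group``."""
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if not {"sequence", "group"} <= set(reader.fieldnames or ()):
            raise CatalogError(
                f"{path}: exception table needs 'sequence' and 'group' columns"
            )
        table = {}
        for row in reader:
            group = row["group"].strip()
            if group not in GROUP_NAMES:
                raise CatalogError(f"{path}: unknown group {group!r}")
            table[row["sequence"].strip()] = group
    return table


def grouping_report(result: ClassificationResult) -> str:
    """Plain-text grouping report, one section per group in the catalog's
    reporting order (MRFa, LRFa, VRFa, PQRFa, IRFa), then unresolved."""
    lines = []
    order = list(GROUP_NAMES) + [
        g for g in result.members if g not in GROUP_NAMES
    ]
    by_id = result.table.set_index("peptide_id")
    for group in order:
        ids = result.members.get(group, [])
        if not ids and group not in GROUP_NAMES:
            continue
        lines.append(f"{group} GROUP ({len(ids)} peptides)")
        for pid in ids:
            lines.append(f"  {pid}\t{by_id.loc[pid, 'sequence']}a")
        lines.append("")
    lines.append(
        f"concordance with curated groups: "
        f"{result.n_concordant}/{result.n_with_ground_truth}"
    )
    return "\n".join(lines) + "\n"
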