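"""Seeded generator of precursor polypeptides with known peptide payloads.

Each synthetic precursor is a string of spacer sequence into which peptide
payloads are embedded with the genuine processing signals: an upstream
mono-basic K/R endoproteolytic site, the payload body, then the amidation
glycine followed by a mono- or dibasic K/R run.  Ground truth records every
payload's 0-based half-open coordinates, motif and expected C-terminal
group, so the prohormone-processing and classification stages can be scored
exactly with no external data.

Spacers are drawn from an alphabet without K, R or G, which makes the truth
unambiguous: every amidation cassette in the sequence is either a payload
or a labeled decoy.  Three decoy kinds probe the failure modes separately:

* ``g-no-basic`` — a glycine not followed by a basic residue (no cassette);
* ``basic-no-g`` — a stray K/R inside a spacer (no cassette);
* ``short-body`` — a real cassette whose body is shorter than the
  processing ``min_len``, placed far enough (> ``max_len``) from any
  upstream basic residue that the length filter removes every candidate.

By default payload bodies are generated de novo with the requested
C-terminal motif and no K/R/G outside it ("random" mode), which guarantees
coordinate-exact recovery.  "catalog" mode samples real cataloged peptides
instead; several of those begin with K or contain internal G-R motifs, so
exact recovery is not guaranteed there (see the methods note).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .catalog import load_peptides
from .classify import classify_peptide
from .processing import annotate_motif

__all__ = [
    "SyntheticError",
    "Payload",
    "Decoy",
    "SyntheticTruth",
    "make_precursor",
    "generate_dataset",
    "write_dataset",
    "SPACER_ALPHABET",
    "child_seed",
]

SPACER_ALPHABET = "ACDEFHILMNPQSTVWY"  # no K, R or G
_BASICS = "KR"
DEFAULT_MOTIF_MIX = {
    "LPXRFa-L": 0.25,
    "LPXRFa-Q": 0.25,
    "PQRFa": 0.25,
    "generic-RFa": 0.25,
}
_MOTIF_SUFFIX = {"LPXRFa-L": "LPLRF", "LPXRFa-Q": "LPQRF", "PQRFa": "PQRF"}
_MOTIF_GROUP = {"LPXRFa-L": "LRFa", "LPXRFa-Q": "PQRFa", "PQRFa": "PQRFa"}
_DECOY_KINDS = ("g-no-basic", "basic-no-g", "short-body")

# processing-rule bounds the decoy placement must respect
_MIN_LEN = 4
_MAX_LEN = 40


class SyntheticError(ValueError):
    """Raised for infeasible generator parameters."""


@dataclass(frozen=True)
class Payload:
    sequence: str
    start: int
    end: int
    motif: str
    group: str


@dataclass(frozen=True)
class Decoy:
    kind: str
    position: int


@dataclass(frozen=True)
class SyntheticTruth:
    precursor_id: str
    payloads: tuple[Payload, ...]
    decoys: tuple[Decoy, ...]
    params: dict
    seed: int


def _random_body(rng: np.random.Generator, motif: str, body_len: tuple[int, int]) -> str:
    lo, hi = body_len
    if motif in _MOTIF_SUFFIX:
        suffix = _MOTIF_SUFFIX[motif]
        length = int(rng.integers(max(lo, len(suffix) + 1), hi + 1))
        while True:
            prefix = "".join(
                rng.choice(list(SPACER_ALPHABET), size=length - len(suffix))
            )
            if motif == "PQRFa" and prefix.endswith("L"):
                continue  # would upgrade PQRF to the LPQRF motif
            return prefix + suffix
    if motif == "generic-RFa":
        length = int(rng.integers(max(lo, 4), hi + 1))
        while True:
            core = "".join(rng.choice(list(SPACER_ALPHABET), size=length - 2))
            if core.endswith(("PQ", "LPL", "LPQ")):
                continue  # would land in a specific motif class
            return core + "RF"
    raise SyntheticError(f"unknown motif {motif!r}")


def _normalize_mix(motif_mix) -> tuple[list[str], list[float]]:
    mix = dict(DEFAULT_MOTIF_MIX if motif_mix is None else motif_mix)
    unknown = set(mix) - set(DEFAULT_MOTIF_MIX)
    if unknown:
        raise SyntheticError(f"unknown motifs in mix: {sorted(unknown)}")
    total = sum(mix.values())
    if not np.isclose(total, 1.0):
        raise SyntheticError("motif_mix proportions must sum to 1")
    names = sorted(mix)
    return names, [mix[n] / total for n in names]


def make_precursor(
    seed: int,
    n_payloads: int = 3,
    motif_mix: dict | None = None,
    spacer_len: tuple[int, int] = (8, 24),
    decoy_rate: float = 0.0,
    mode: str = "random",
    body_len: tuple[int, int] = (4, 20),
    precursor_id: str = "synthetic-1",
) -> tuple[str, SyntheticTruth]:
    """Generate one precursor sequence plus its ground truth."""
    if n_payloads < 1:
        raise SyntheticError("n_payloads must be >= 1")
    if spacer_len[0] < 1 or spacer_len[0] > spacer_len[1]:
        raise SyntheticError("spacer_len must satisfy 1 <= lo <= hi")
    if not 0.0 <= decoy_rate <= 1.0:
        raise SyntheticError("decoy_rate must be a proportion in [0, 1]")
    if mode not in ("random", "catalog"):
        raise SyntheticError(f"unknown mode {mode!r}")
    motif_names, motif_probs = _normalize_mix(motif_mix)
    rng = np.random.default_rng(seed)
    catalog_pool = load_peptides() if mode == "catalog" else None

    chars: list[str] = []
    payloads: list[Payload] = []
    decoys: list[Decoy] = []
    last_basic = -(10**9)

    def emit(s: str) -> None:
        chars.extend(s)

    def emit_spacer_with_decoy() -> None:
        nonlocal last_basic
        length = int(rng.integers(spacer_len[0], spacer_len[1] + 1))
        spacer = list(rng.choice(list(SPACER_ALPHABET), size=max(length, 1)))
        kind = None
        if decoy_rate > 0 and rng.random() < decoy_rate:
            kind = _DECOY_KINDS[int(rng.integers(0, len(_DECOY_KINDS)))]
        if kind == "g-no-basic":
            if len(spacer) < 2:
                spacer.append(str(rng.choice(list(SPACER_ALPHABET))))
            idx = int(rng.integers(0, len(spacer) - 1))
            spacer.insert(idx, "G")  # followed by a spacer residue, never K/R
            decoys.append(Decoy("g-no-basic", len(chars) + idx))
            emit("".join(spacer))
        elif kind == "basic-no-g":
            idx = int(rng.integers(0, len(spacer) + 1))
            basic = str(rng.choice(list(_BASICS)))
            spacer.insert(idx, basic)
            decoys.append(Decoy("basic-no-g", len(chars) + idx))
            emit("".join(spacer))
            last_basic = max(last_basic, len(chars) - (len(spacer) - idx))
        elif kind == "short-body":
            emit("".join(spacer))
            body_n = int(rng.integers(1, _MIN_LEN))
            # every upstream basic must leave a body longer than max_len so
            # the length filter removes all candidate calls
            glycine_at = lambda: len(chars) + 1 + body_n
            while glycine_at() - last_basic - 1 <= _MAX_LEN:
                emit(str(rng.choice(list(SPACER_ALPHABET))))
            emit(str(rng.choice(list(_BASICS))))
            emit("".join(rng.choice(list(SPACER_ALPHABET), size=body_n)))
            decoys.append(Decoy("short-body", len(chars)))
            emit("G")
            run = int(rng.integers(1, 3))
            emit("".join(rng.choice(list(_BASICS), size=run)))
            last_basic = len(chars) - 1
        else:
            emit("".join(spacer))

    for _ in range(n_payloads):
        emit_spacer_with_decoy()
        emit(str(rng.choice(list(_BASICS))))  # upstream endoproteolytic site
        if mode == "catalog":
            record = catalog_pool[int(rng.integers(0, len(catalog_pool)))]
            body = record.sequence
            motif = annotate_motif(body)
            group = record.reference_group or classify_peptide(body).group
        else:
            motif = motif_names[
                int(rng.choice(len(motif_names), p=motif_probs))
            ]
            body = _random_body(rng, motif, body_len)
            group = _MOTIF_GROUP.get(motif) or classify_peptide(body).group
        start = len(chars)
        emit(body)
        end = len(chars)
        payloads.append(Payload(body, start, end, motif, group))
        emit("G")
        run = int(rng.integers(1, 3))
        emit("".join(rng.choice(list(_BASICS), size=run)))
        last_basic = len(chars) - 1
    emit_spacer_with_decoy()  # trailing spacer slot

    params = {
        "n_payloads": n_payloads,
        "motif_mix": dict(zip(motif_names, motif_probs)),
        "spacer_len": list(spacer_len),
        "decoy_rate": decoy_rate,
        "mode": mode,
        "body_len": list(body_len),
    }
    truth = SyntheticTruth(
        precursor_id=precursor_id,
        payloads=tuple(payloads),
        decoys=tuple(decoys),
        params=params,
        seed=seed,
    )
    return "".join(chars), truth


def child_seed(master_seed: int, index: int) -> int:
    """Per-record seed: a fixed integer mix of master seed and index, so
    partial regeneration of a dataset is stable."""
    return (master_seed * 1_000_003 + 10_007 * index + 1) % 2_147_483_647


def generate_dataset(
    n_precursors: int,
    seed: int,
    **params,
) -> list[tuple[str, str, SyntheticTruth]]:
    """Generate ``n_precursors`` records: (precursor_id, sequence, truth)."""
    if n_precursors < 1:
        raise SyntheticError("n_precursors must be >= 1")
    out = []
    for i in range(n_precursors):
        pid = f"synthetic-{i + 1}"
        seq, truth = make_precursor(
            seed=child_seed(seed, i), precursor_id=pid, **params
        )
        out.append((pid, seq, truth))
    return out


def write_dataset(
    records: Sequence[tuple[str, str, SyntheticTruth]],
    fasta_path: str | Path,
    truth_path: str | Path,
    config_path: str | Path | None = None,
    force: bool = False,
    master_seed: int | None = None,
) -> None:
    """Write a dataset as multi-FASTA + truth TSV (+ sidecar config)."""
    for p in (fasta_path, truth_path, config_path):
        if p is not None and Path(p).exists() and not force:
            raise SyntheticError(f"output path exists: {p} (use force=True)")
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for pid, seq, _ in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("precursor_id\tstart\tend\tsequence\tmotif\tgroup\tkind\n")
        for pid, _, truth in records:
            for p in truth.payloads:
                fh.write(
                    f"{pid}\t{p.start}\t{p.end}\t{p.sequence}\t{p.motif}"
                    f"\t{p.group}\tpayload\n"
                )
            for d in truth.decoys:
                fh.write(f"{pid}\t{d.position}\t\t\t\t\t{d.kind}\n")
    if config_path is not None:
        cfg = {
            "n_precursors": len(records),
            "master_seed": master_seed,
            "record_seeds": [t.seed for _, _, t in records],
            "params": records[0][2].params if records else {},
        }
        with open(config_path, "w", encoding="utf-8") as fh:
            json.dump(cfg, fh, indent=2, sort_keys=True)
            fh.write("\n")
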