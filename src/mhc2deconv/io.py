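"""Readers and writers for the plain-text formats the tool touches.

All tables are TSV with a header line; lines starting with ``#`` are
metadata comments and are skipped on read.  Proteins are standard FASTA.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .datamodel import (
    VALID_CHARS,
    AlleleSpec,
    PeptideRecord,
    PositionProfile,
    ProteinRecord,
)
from .network import transform_ba_target

logger = logging.getLogger(__name__)


def read_fasta(path) -> list[ProteinRecord]:
    """Read proteins from FASTA; non-alphabet characters map to X (warned)."""
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        cleaned = "".join(c if c in VALID_CHARS else "X" for c in seq)
        if cleaned != seq:
            n_bad = sum(a != b for a, b in zip(seq, cleaned))
            logger.warning(
                "protein %s: %d non-standard residue(s) mapped to X", entry.id, n_bad
            )
        records.append(ProteinRecord(id=entry.id, sequence=cleaned))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(proteins: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for prot in proteins:
            fh.write(f">{prot.id}\n")
            for i in range(0, len(prot.sequence), 60):
                fh.write(prot.sequence[i : i + 60] + "\n")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_peptide_table(path, strict: bool = True) -> list[PeptideRecord]:
    """Parse a peptide TSV into records.

    Mandatory column: ``peptide``.  Recognized optional columns:

    * ``target`` -- training label.  Interpreted per ``kind``: for BA rows an
      IC50 in nM (log-transformed to [0, 1]), for EL rows 1/0.
    * ``kind``   -- BA | EL_positive | EL_negative (default EL, label by target).
    * ``allele`` -- restriction for single-allele rows.
    * ``context`` or ``protein_id`` + ``start``.

    With ``strict=False`` malformed rows are logged and dropped instead of
    raising.
    """
    df = _read_tsv(path)
    if "peptide" not in df.columns:
        raise ValueError(f"missing mandatory column 'peptide' in {path}")
    records: list[PeptideRecord] = []
    for i, row in df.iterrows():
        try:
            kind = str(row["kind"]) if "kind" in df.columns and pd.notna(row.get("kind")) else None
            raw_target = row.get("target")
            if kind == "BA":
                target = transform_ba_target(float(raw_target))
            else:
                target = float(raw_target) if pd.notna(raw_target) else 1.0
                if kind is None:
                    kind = "EL_positive" if target >= 0.5 else "EL_negative"
            start = row.get("start")
            records.append(
                PeptideRecord(
                    sequence=str(row["peptide"]),
                    source_kind=kind,
                    target=target,
                    context=(str(row["context"]) if "context" in df.columns and pd.notna(row.get("context")) else None),
                    source_protein_id=(str(row["protein_id"]) if "protein_id" in df.columns and pd.notna(row.get("protein_id")) else None),
                    start=int(start) if pd.notna(start) else None,
                    allele=(str(row["allele"]) if "allele" in df.columns and pd.notna(row.get("allele")) else None),
                )
            )
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"row {i} of {path}: {exc}") from exc
            logger.warning("rejected row %d of %s: %s", i, path, exc)
    return records


def write_peptide_table(records: list[PeptideRecord], path, comment: str | None = None) -> None:
    """Write records as TSV.  BA targets are written back as IC50 is not
    recoverable, so the transformed [0, 1] target is stored with kind=BA_t."""
    rows = []
    for r in records:
        rows.append(
            {
                "peptide": r.sequence,
                "kind": r.source_kind,
                "target": r.target,
                "context": r.context if r.context is not None else "",
                "protein_id": r.source_protein_id or "",
                "start": r.start if r.start is not None else "",
                "allele": r.allele or "",
            }
        )
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_peptide_table_raw(path, strict: bool = True) -> list[PeptideRecord]:
    """Read a table previously produced by :func:`write_peptide_table`
    (targets already transformed; exact round-trip)."""
    df = _read_tsv(path)
    if "peptide" not in df.columns:
        raise ValueError(f"missing mandatory column 'peptide' in {path}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                PeptideRecord(
                    sequence=str(row["peptide"]),
                    source_kind=str(row["kind"]),
                    target=float(row["target"]),
                    context=str(row["context"]) if pd.notna(row.get("context")) and str(row.get("context")) else None,
                    source_protein_id=str(row["protein_id"]) if pd.notna(row.get("protein_id")) and str(row.get("protein_id")) else None,
                    start=int(float(row["start"])) if pd.notna(row.get("start")) and str(row.get("start")) else None,
                    allele=str(row["allele"]) if pd.notna(row.get("allele")) and str(row.get("allele")) else None,
                )
            )
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"row {i} of {path}: {exc}") from exc
            logger.warning("rejected row %d of %s: %s", i, path, exc)
    return records


def read_allele_table(path) -> dict[str, AlleleSpec]:
    """Read allele -> pseudo-sequence TSV (columns allele, pseudo_sequence).

    Lookup keys are case-normalized (upper).  All pseudo-sequences must share
    one length; exact duplicates are deduplicated, conflicting duplicates are
    an error.
    """
    df = _read_tsv(path)
    for col in ("allele", "pseudo_sequence"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    table: dict[str, AlleleSpec] = {}
    for _, row in df.iterrows():
        name = str(row["allele"]).strip()
        key = name.upper()
        spec = AlleleSpec(name=name, pseudo_sequence=str(row["pseudo_sequence"]).strip())
        if key in table:
            if table[key].pseudo_sequence != spec.pseudo_sequence:
                raise ValueError(f"conflicting pseudo-sequences for allele {name}")
            continue
        table[key] = spec
    lengths = {k: len(v.pseudo_sequence) for k, v in table.items()}
    if len(set(lengths.values())) > 1:
        # majority length wins; ties resolve to the first allele's length
        counts: dict[int, int] = {}
        for length in lengths.values():
            counts[length] = counts.get(length, 0) + 1
        common = max(counts, key=lambda l: (counts[l], l == next(iter(lengths.values()))))
        offending = sorted(k for k, l in lengths.items() if l != common)
        raise ValueError(f"pseudo-sequence length mismatch for alleles: {offending}")
    return table


def write_allele_table(alleles: list[AlleleSpec], path) -> None:
    pd.DataFrame(
        {"allele": [a.name for a in alleles], "pseudo_sequence": [a.pseudo_sequence for a in alleles]}
    ).to_csv(path, sep="\t", index=False)


def write_profile(profile: PositionProfile, path, comment: str | None = None) -> None:
    """Profile TSV: protein_id, 1-based position, value, kind."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        pd.DataFrame(
            {
                "protein_id": profile.protein_id,
                "position": range(1, len(profile) + 1),
                "value": profile.values,
                "kind": profile.kind,
            }
        ).to_csv(fh, sep="\t", index=False)


def read_profile(path) -> PositionProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.sort_values("position")
    return PositionProfile(
        protein_id=str(df["protein_id"].iloc[0]),
        values=df["value"].to_numpy(dtype=float),
        kind=str(df["kind"].iloc[0]),
    )
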