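"""Standard-format I/O: clone FASTA with provenance headers, truth tables,
allele FASTA and alignment reading.

Clone FASTA header dialect::

    >cloneID|animal=<ID>|locus=<A|B>|batch=<ID>
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohort import AlleleSequence, CloneOrigin, CloneRecord, Locus, SyntheticTruth
from .diversity import SiteAlignment

logger = logging.getLogger(__name__)

TRUTH_COLUMNS = ("clone_id", "origin_type", "source_allele", "parent2", "breakpoint", "n_errors")


class HeaderError(ValueError):
    """A clone FASTA header does not follow the provenance dialect."""


def clone_header(clone: CloneRecord) -> str:
    return f"{clone.clone_id}|animal={clone.animal}|locus={clone.locus.value}|batch={clone.pcr_batch}"


def parse_clone_header(header: str) -> tuple[str, str, Locus, str]:
    parts = header.split("|")
    if len(parts) != 4:
        raise HeaderError(f"malformed clone header: {header!r}")
    clone_id = parts[0]
    fields = {}
    for part in parts[1:]:
        if "=" not in part:
            raise HeaderError(f"malformed field {part!r} in header of {clone_id}")
        key, value = part.split("=", 1)
        fields[key] = value
    missing = {"animal", "locus", "batch"} - fields.keys()
    if missing:
        raise HeaderError(f"header of {clone_id} missing field(s): {sorted(missing)}")
    try:
        locus = Locus(fields["locus"])
    except ValueError as exc:
        raise HeaderError(f"unknown locus {fields['locus']!r} in header of {clone_id}") from exc
    return clone_id, fields["animal"], locus, fields["batch"]


def write_clone_fasta(clones: Iterable[CloneRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.seq), id=clone_header(c), description="") for c in clones
    ]
    SeqIO.write(records, str(path), "fasta")


def read_clone_fasta(path: str | Path, strict: bool = True) -> tuple[tuple[CloneRecord, ...], tuple[str, ...]]:
    """Read a clone library; returns (records, malformed-header messages).

    In strict mode any malformed header raises, naming the record.
    """
    records: list[CloneRecord] = []
    errors: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            clone_id, animal, locus, batch = parse_clone_header(rec.id)
        except HeaderError as exc:
            if strict:
                raise
            errors.append(str(exc))
            continue
        records.append(CloneRecord(clone_id, animal, locus, batch, str(rec.seq).upper()))
    if errors:
        logger.warning("%d malformed clone header(s) skipped", len(errors))
    return tuple(records), tuple(errors)


def write_allele_fasta(alleles: Iterable, path: str | Path) -> None:
    """Write named allele sequences (anything with .name and .seq)."""
    records = [SeqRecord(Seq(a.seq), id=a.name, description="") for a in alleles]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(path: str | Path, exon_boundary: int = 270) -> SiteAlignment:
    """Read an equal-length aligned FASTA into a SiteAlignment."""
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not names:
        raise ValueError(f"no sequences in {path}")
    return SiteAlignment.from_sequences(names, seqs, exon_boundary)


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    rows = [
        {
            "clone_id": cid,
            "origin_type": o.origin_type,
            "source_allele": o.source_allele,
            "parent2": o.parent2 if o.parent2 is not None else "",
            "breakpoint": o.breakpoint if o.breakpoint is not None else "",
            "n_errors": o.n_errors,
        }
        for cid, o in truth.clone_origin.items()
    ]
    pd.DataFrame(rows, columns=list(TRUTH_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> dict[str, CloneOrigin]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, CloneOrigin] = {}
    for row in df.itertuples(index=False):
        out[row.clone_id] = CloneOrigin(
            origin_type=row.origin_type,
            source_allele=row.source_allele,
            parent2=row.parent2 or None,
            breakpoint=int(row.breakpoint) if row.breakpoint else None,
            n_errors=int(row.n_errors) if row.n_errors else 0,
        )
    return out


def write_pool_fasta(pool: Sequence[AlleleSequence], path: str | Path) -> None:
    write_allele_fasta(pool, path)
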