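"""Back-splice-junction (BSJ) call parsing and consensus circRNA detection.

Two caller dialects are supported. ``caller_a`` (CIRI2-like) reports 1-based
inclusive coordinates together with junction-spanning and host-linear read
counts; ``caller_b`` (find_circ-like) reports BED-style 0-based half-open
coordinates and junction reads only. A circRNA enters the consensus set when
it is detected by caller A with enough junction reads in total AND it is
corroborated either by caller B or by membership in a public circRNA database
(circAtlas / CIRCpedia / circBase style lists).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

VALID_STRANDS = frozenset({"+", "-"})
CALLER_A = "caller_a"
CALLER_B = "caller_b"

CALLER_A_COLUMNS = [
    "circ_id",
    "chrom",
    "start",
    "end",
    "strand",
    "junction_reads",
    "host_linear_reads",
    "host_gene",
]


class BsjParseError(ValueError):
    """Malformed BSJ table row; message names the offending line."""


@dataclass(frozen=True, order=True)
class CircId:
    """Genomic identity of a back-splice junction (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid coordinates {self.chrom}:{self.start}-{self.end}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def from_string(cls, text: str) -> "CircId":
        locus, strand = text.rsplit(":", 1)
        chrom, span = locus.rsplit(":", 1)
        start, end = span.split("-")
        return cls(chrom, int(start), int(end), strand)

    @classmethod
    def from_bed(cls, chrom: str, bed_start: int, bed_end: int, strand: str) -> "CircId":
        """Convert 0-based half-open BED coordinates to internal 1-based inclusive."""
        return cls(chrom, bed_start + 1, bed_end, strand)


@dataclass(frozen=True)
class BsjCall:
    """One caller's detection of one circRNA in one sample."""

    circ_id: CircId
    sample_id: str
    caller: str
    junction_reads: int
    host_linear_reads: Optional[int] = None
    host_gene: str = "unknown"

    def __post_init__(self) -> None:
        if self.caller not in (CALLER_A, CALLER_B):
            raise ValueError(f"unknown caller {self.caller!r}")
        if self.junction_reads < 0:
            raise ValueError("junction_reads must be non-negative")
        if self.caller == CALLER_B and self.host_linear_reads is not None:
            raise ValueError("caller_b calls carry no host_linear_reads")
        if self.host_linear_reads is not None and self.host_linear_reads < 0:
            raise ValueError("host_linear_reads must be non-negative")


@dataclass
class AnnotationDB:
    """circRNA database membership: CircId -> subset of database names."""

    membership: dict[CircId, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, dbs in self.membership.items():
            if not dbs:
                raise ValueError(f"empty membership set for {cid}")

    def __contains__(self, cid: CircId) -> bool:
        return cid in self.membership

    @classmethod
    def from_tables(cls, paths: Iterable[Path | str]) -> "AnnotationDB":
        """Load one BED-like TSV per database.

        Each file declares its coordinate convention in a first header line
        ``#coords=one-based`` or ``#coords=bed`` and then carries columns
        chrom, start, end, strand, db_name.
        """
        membership: dict[CircId, set[str]] = {}
        for path in paths:
            path = Path(path)
            with open(path) as fh:
                header = fh.readline().strip()
                if not header.startswith("#coords="):
                    raise BsjParseError(f"{path}: missing #coords= header line")
                convention = header.split("=", 1)[1]
                if convention not in ("one-based", "bed"):
                    raise BsjParseError(f"{path}: unknown coordinate convention {convention!r}")
                for lineno, line in enumerate(fh, start=2):
                    line = line.strip()
                    if not line:
                        continue
                    parts = line.split("\t")
                    if len(parts) < 5:
                        raise BsjParseError(f"{path} line {lineno}: expected 5 columns")
                    chrom, start, end, strand, db_name = parts[:5]
                    if strand not in VALID_STRANDS:
                        raise BsjParseError(f"{path} line {lineno}: bad strand {strand!r}")
                    if convention == "bed":
                        cid = CircId.from_bed(chrom, int(start), int(end), strand)
                    else:
                        cid = CircId(chrom, int(start), int(end), strand)
                    membership.setdefault(cid, set()).add(db_name)
        return cls({cid: frozenset(dbs) for cid, dbs in membership.items()})


@dataclass
class ConsensusSet:
    """circRNAs surviving the consensus rule, with caller-A count matrices."""

    ids: list[CircId]
    circ_counts: pd.DataFrame  # circRNAs x samples, caller_a junction reads
    host_linear_counts: pd.DataFrame  # matching matrix of host-linear reads
    host_genes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.circ_counts.columns.equals(self.host_linear_counts.columns):
            raise ValueError("circ and host-linear matrices must share sample columns")


def _int_field(value, what: str, path, lineno: int) -> int:
    try:
        out = int(value)
    except (TypeError, ValueError):
        raise BsjParseError(f"{path} line {lineno}: non-integer {what} {value!r}") from None
    if out < 0:
        raise BsjParseError(f"{path} line {lineno}: negative {what}")
    return out


def parse_bsj_table(path: Path | str, dialect: str, sample_id: Optional[str] = None) -> list[BsjCall]:
    """Parse one per-sample BSJ table in either caller dialect.

    ``sample_id`` defaults to the file stem (before the first ``__``).
    Strand "." is rejected explicitly: an unstranded back-splice junction has
    no usable identity downstream.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem.split("__")[0]
    calls: list[BsjCall] = []
    if dialect == CALLER_A:
        table = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in CALLER_A_COLUMNS if c not in table.columns]
        if missing:
            raise BsjParseError(f"{path}: missing columns {missing}")
        for i, row in enumerate(table.itertuples(index=False), start=2):
            strand = row.strand
            if strand == ".":
                raise BsjParseError(f"{path} line {i}: unstranded record rejected")
            if strand not in VALID_STRANDS:
                raise BsjParseError(f"{path} line {i}: bad strand {strand!r}")
            cid = CircId(row.chrom, _int_field(row.start, "start", path, i),
                         _int_field(row.end, "end", path, i), strand)
            calls.append(
                BsjCall(
                    circ_id=cid,
                    sample_id=sample_id,
                    caller=CALLER_A,
                    junction_reads=_int_field(row.junction_reads, "junction_reads", path, i),
                    host_linear_reads=_int_field(row.host_linear_reads, "host_linear_reads", path, i),
                    host_gene=row.host_gene,
                )
            )
    elif dialect == CALLER_B:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("track"):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise BsjParseError(f"{path} line {lineno}: expected >= 6 BED columns")
                chrom, bed_start, bed_end, _name, score, strand = parts[:6]
                if strand == ".":
                    raise BsjParseError(f"{path} line {lineno}: unstranded record rejected")
                if strand not in VALID_STRANDS:
                    raise BsjParseError(f"{path} line {lineno}: bad strand {strand!r}")
                cid = CircId.from_bed(chrom, _int_field(bed_start, "start", path, lineno),
                                      _int_field(bed_end, "end", path, lineno), strand)
                calls.append(
                    BsjCall(
                        circ_id=cid,
                        sample_id=sample_id,
                        caller=CALLER_B,
                        junction_reads=_int_field(score, "junction_reads", path, lineno),
                    )
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return calls


def consensus_filter(
    calls: Iterable[BsjCall],
    db: AnnotationDB,
    min_reads: int = 2,
    per_sample: bool = False,
) -> ConsensusSet:
    """Apply the consensus detection rule.

    A CircId is retained iff caller A's junction reads total at least
    ``min_reads`` (summed across all samples by default; with
    ``per_sample=True`` some single sample must reach the floor) AND the id is
    corroborated by caller B in any sample or by any database.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no BSJ calls supplied")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")

    a_reads: dict[CircId, dict[str, int]] = {}
    a_linear: dict[CircId, dict[str, int]] = {}
    hosts: dict[CircId, str] = {}
    b_ids: set[CircId] = set()
    sample_ids: set[str] = set()
    for call in calls:
        if call.caller == CALLER_A:
            sample_ids.add(call.sample_id)
            a_reads.setdefault(call.circ_id, {})
            a_reads[call.circ_id][call.sample_id] = (
                a_reads[call.circ_id].get(call.sample_id, 0) + call.junction_reads
            )
            a_linear.setdefault(call.circ_id, {})
            a_linear[call.circ_id][call.sample_id] = (
                a_linear[call.circ_id].get(call.sample_id, 0) + (call.host_linear_reads or 0)
            )
            if call.host_gene not in ("unknown", "") and call.circ_id not in hosts:
                hosts[call.circ_id] = call.host_gene
        else:
            b_ids.add(call.circ_id)

    retained: list[CircId] = []
    for cid in sorted(a_reads, key=str):
        per_sample_reads = a_reads[cid]
        if per_sample:
            enough = max(per_sample_reads.values(), default=0) >= min_reads
        else:
            enough = sum(per_sample_reads.values()) >= min_reads
        if enough and (cid in b_ids or cid in db):
            retained.append(cid)

    columns = sorted(sample_ids)
    index = [str(cid) for cid in retained]
    circ = pd.DataFrame(0, index=index, columns=columns, dtype=np.int64)
    lin = pd.DataFrame(0, index=index, columns=columns, dtype=np.int64)
    for cid in retained:
        key = str(cid)
        for sid, reads in a_reads[cid].items():
            circ.loc[key, sid] = reads
        for sid, reads in a_linear[cid].items():
            lin.loc[key, sid] = reads
    host_genes = {str(cid): hosts.get(cid, "unannotated") for cid in retained}
    return ConsensusSet(ids=retained, circ_counts=circ, host_linear_counts=lin, host_genes=host_genes)


def isoforms_per_gene(cs: ConsensusSet, host_map: Optional[Mapping[str, str]] = None) -> pd.Series:
    """Count distinct retained circRNA isoforms per host gene.

    Genes with zero retained isoforms are absent; unknown hosts are grouped
    under "unannotated".
    """
    hosts = dict(cs.host_genes)
    if host_map is not None:
        hosts.update({k: v for k, v in host_map.items() if k in hosts})
    counts: dict[str, int] = {}
    for cid in cs.ids:
        gene = hosts.get(str(cid), "unannotated") or "unannotated"
        counts[gene] = counts.get(gene, 0) + 1
    return pd.Series(counts, dtype=np.int64).sort_index()


def circ_exceeds_linear_fraction(cs: ConsensusSet) -> float:
    """Fraction of retained circRNAs whose total junction reads strictly exceed
    their total host-linear reads (ties count as not exceeding)."""
    if not cs.ids:
        raise ValueError("empty consensus set")
    circ_totals = cs.circ_counts.sum(axis=1).to_numpy()
    lin_totals = cs.host_linear_counts.sum(axis=1).to_numpy()
    return float(np.mean(circ_totals > lin_totals))
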