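"""Readers and writers for gene tables, domain tables and protein FASTA,
plus resolution of raw domain hits into clean per-protein architectures.

Supported formats
-----------------
genes:    GFF3 (1-based inclusive; CDS features with a ``protein_id``
          attribute become coding records, pseudogene/RNA features become
          non-coding records) or a plain TSV with header
          ``gene_id  replicon  start  end  strand  protein_id``.
domains:  HMMER3 ``hmmscan --domtblout`` text, or a TSV with header
          ``protein_id  domain  start  end  evalue  score``.
proteins: FASTA (Biopython).

Rows above the e-value threshold (default 1e-5) are dropped on read and
counted; the threshold is a uniform config default.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

from .model import DomainHit, GeneRecord, Genome, ProteinArchitecture

log = logging.getLogger(__name__)

DEFAULT_EVALUE = 1e-5
DEFAULT_OVERLAP_FRAC = 0.2

_NONCODING_TYPES = {"pseudogene", "tRNA", "rRNA", "ncRNA", "tmRNA", "SRP_RNA"}
_PF_RE = re.compile(r"^PF\d{5}", re.IGNORECASE)


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

def read_gene_table(path, fmt: str = "auto", genome_id: Optional[str] = None) -> Genome:
    """Read an ordered gene table into a :class:`~sigcensus.model.Genome`.

    Genes are sorted by start coordinate within each replicon and ordinals
    are assigned in that order, regardless of file order.  Duplicate gene
    ids are a hard error; out-of-order input is sorted with a log message.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if genome_id is None:
        genome_id = path.stem.replace(".genes", "")
    rows = _read_gff3_rows(path) if fmt == "gff3" else _read_tsv_rows(path)
    if not rows:
        log.warning("gene table %s is empty", path)
        return Genome(genome_id, {})

    by_rep: dict[str, list[dict]] = {}
    for row in rows:
        by_rep.setdefault(row["replicon"], []).append(row)

    replicons: dict[str, list[GeneRecord]] = {}
    for rep_id, rep_rows in by_rep.items():
        starts = [r["start"] for r in rep_rows]
        if starts != sorted(starts):
            log.info("replicon %s: genes out of coordinate order; sorting", rep_id)
        rep_rows.sort(key=lambda r: (r["start"], r["end"], r["gene_id"]))
        replicons[rep_id] = [
            GeneRecord(
                gene_id=r["gene_id"],
                replicon_id=rep_id,
                ordinal=i,
                start=r["start"],
                end=r["end"],
                strand=r["strand"],
                protein_id=r["protein_id"],
            )
            for i, r in enumerate(rep_rows)
        ]
    return Genome(genome_id, replicons)


def _read_gff3_rows(path: Path) -> list[dict]:
    rows, seen = [], set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype == "CDS":
                protein_id = (feat.attributes.get("protein_id") or [None])[0]
            elif feat.featuretype in _NONCODING_TYPES:
                protein_id = None
            else:
                # 'gene'/'region' parents would double-count their CDS children
                continue
            gene_id = (feat.attributes.get("ID") or feat.attributes.get("locus_tag") or [None])[0]
            if gene_id is None:
                log.warning("GFF3 feature without ID skipped: %s", line[:80])
                continue
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id!r} in {path}")
            seen.add(gene_id)
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            rows.append(
                dict(gene_id=gene_id, replicon=feat.seqid, start=feat.start,
                     end=feat.end, strand=strand, protein_id=protein_id)
            )
    return rows


def _read_tsv_rows(path: Path) -> list[dict]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    required = {"gene_id", "replicon", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene TSV {path} missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in {path}")
    rows = []
    for r in df.itertuples(index=False):
        pid = getattr(r, "protein_id", None)
        if pd.isna(pid) or pid in ("", "-"):
            pid = None
        rows.append(
            dict(gene_id=r.gene_id, replicon=r.replicon, start=int(r.start),
                 end=int(r.end), strand=r.strand, protein_id=pid)
        )
    return rows


def write_gene_table(genome: Genome, path, fmt: str = "auto") -> None:
    """Write a genome back out (TSV or GFF3); round-trips with the reader."""
    path = Path(path)
    if fmt == "auto":
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if fmt == "tsv":
        rows = [
            dict(gene_id=g.gene_id, replicon=g.replicon_id, start=g.start,
                 end=g.end, strand=g.strand, protein_id=g.protein_id or "")
            for g in genome.genes()
        ]
        pd.DataFrame(
            rows, columns=["gene_id", "replicon", "start", "end", "strand", "protein_id"]
        ).to_csv(path, sep="\t", index=False)
        return
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes():
            if g.is_coding:
                ftype = "CDS"
                attrs = f"ID={g.gene_id};protein_id={g.protein_id}"
            else:
                ftype = "pseudogene"
                attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.replicon_id}\tsigcensus\t{ftype}\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# domain tables
# ---------------------------------------------------------------------------

def read_domain_table(
    path, dialect: str = "auto", evalue_threshold: Optional[float] = DEFAULT_EVALUE
) -> list[DomainHit]:
    """Read a domain table; rows above the e-value threshold are dropped.

    ``evalue_threshold=None`` keeps everything (equivalent to infinity);
    the filtered output at any finite threshold is always a subset of the
    unfiltered output.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"domain table not found: {path}")
    if dialect == "auto":
        dialect = _sniff_domain_dialect(path)
    if evalue_threshold is None:
        evalue_threshold = math.inf
    raw = _parse_domtblout(path) if dialect == "domtblout" else _parse_domain_tsv(path)
    kept = [h for h in raw if h.e_value <= evalue_threshold]
    dropped = len(raw) - len(kept)
    if dropped:
        log.info("%s: dropped %d/%d hits above e-value %.3g",
                 path.name, dropped, len(raw), evalue_threshold)
    return kept


def _sniff_domain_dialect(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("#"):
                return "domtblout"
            return "domtblout" if len(line.split()) >= 22 else "tsv"
    return "tsv"


def _parse_domtblout(path: Path) -> list[DomainHit]:
    """Parse HMMER3 ``hmmscan --domtblout``: target = HMM, query = protein.

    Uses the per-domain independent e-value (column 13) and envelope
    coordinates (columns 20-21).
    """
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split(None, 22)
            if len(f) < 22:
                log.warning("%s:%d malformed domtblout row skipped", path.name, ln)
                continue
            try:
                acc = "" if f[1] == "-" else f[1]
                hits.append(
                    DomainHit(
                        protein_id=f[3], accession=acc, name=f[0],
                        env_start=int(f[19]), env_end=int(f[20]),
                        e_value=float(f[12]), bit_score=float(f[13]),
                    )
                )
            except (ValueError, IndexError):
                log.warning("%s:%d malformed domtblout row skipped", path.name, ln)
    return hits


def _parse_domain_tsv(path: Path) -> list[DomainHit]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    required = {"protein_id", "domain", "start", "end", "evalue", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain TSV {path} missing columns: {sorted(missing)}")
    hits = []
    for ln, r in enumerate(df.itertuples(index=False), 2):
        try:
            dom = str(r.domain)
            acc = dom if _PF_RE.match(dom) else ""
            hits.append(
                DomainHit(
                    protein_id=str(r.protein_id), accession=acc, name=dom,
                    env_start=int(r.start), env_end=int(r.end),
                    e_value=float(r.evalue), bit_score=float(r.score),
                )
            )
        except ValueError:
            log.warning("%s:%d malformed domain row skipped", path.name, ln)
    return hits


def write_domain_table(hits: list[DomainHit], path) -> None:
    rows = [
        dict(protein_id=h.protein_id, domain=h.name or h.accession, start=h.env_start,
             end=h.env_end, evalue=h.e_value, score=h.bit_score)
        for h in hits
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "domain", "start", "end", "evalue", "score"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / metadata
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_metadata(path) -> dict[str, dict]:
    """Genome metadata TSV: ``genome_id  ecotype [species] [genome_size]``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "genome_id" not in df.columns:
        raise ValueError(f"metadata {path} lacks a genome_id column")
    out = {}
    for r in df.to_dict(orient="records"):
        gid = r.pop("genome_id")
        out[gid] = {k: v for k, v in r.items() if pd.notna(v)}
    return out


# ---------------------------------------------------------------------------
# architecture resolution
# ---------------------------------------------------------------------------

def resolve_architecture(
    hits: list[DomainHit],
    max_overlap_frac: float = DEFAULT_OVERLAP_FRAC,
    sequence: Optional[str] = None,
    length_aa: Optional[int] = None,
) -> ProteinArchitecture:
    """Resolve raw hits on one protein into a clean architecture.

    Greedy selection by descending bit score; a candidate is rejected when
    it overlaps an already-accepted hit by more than ``max_overlap_frac`` of
    the shorter interval.  The result is maximal: no rejected hit could be
    added back without violating the overlap policy.  Ties in score are
    broken by (start, end, name) so resolution is deterministic.
    """
    if not hits:
        return ProteinArchitecture(protein_id="", domains=[], sequence=sequence,
                                   length_aa=length_aa)
    pids = {h.protein_id for h in hits}
    if len(pids) > 1:
        raise ValueError(f"hits from multiple proteins: {sorted(pids)}")
    pid = hits[0].protein_id
    if sequence is not None:
        length_aa = len(sequence)
        usable = []
        for h in hits:
            if h.env_end > len(sequence):
                log.warning("%s: hit %s env_end %d beyond sequence length %d; dropped",
                            pid, h.name, h.env_end, len(sequence))
            else:
                usable.append(h)
        hits = usable

    accepted: list[DomainHit] = []
    for cand in sorted(hits, key=lambda h: (-h.bit_score, h.env_start, h.env_end, h.name)):
        if all(_overlap_ok(cand, a, max_overlap_frac) for a in accepted):
            accepted.append(cand)
    return ProteinArchitecture(protein_id=pid, domains=accepted,
                               sequence=sequence, length_aa=length_aa)


def _overlap_ok(a: DomainHit, b: DomainHit, frac: float) -> bool:
    shorter = min(a.length, b.length)
    return a.overlap(b) <= frac * shorter


def resolve_all(
    hits: list[DomainHit],
    sequences: Optional[dict[str, str]] = None,
    max_overlap_frac: float = DEFAULT_OVERLAP_FRAC,
) -> dict[str, ProteinArchitecture]:
    """Group hits by protein and resolve each into an architecture."""
    sequences = sequences or {}
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    return {
        pid: resolve_architecture(phits, max_overlap_frac, sequence=sequences.get(pid))
        for pid, phits in by_protein.items()
    }
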