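"""Core domain types shared by every census module.

The coordinate conventions used throughout the package:

* nucleotide coordinates are 1-based, inclusive (GFF3 convention);
* amino-acid positions are 1-based, inclusive;
* gene order on a replicon is captured by a 0-based ``ordinal``, and the
  "distance" between two genes is the number of *intervening* genes,
  ``|ordinal_a - ordinal_b| - 1``, strand-ignored.  Genes on different
  replicons are infinitely far apart.  Every neighborhood rule in the
  package ("within four genes", "more than four genes away") is expressed
  in this distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

INF = math.inf


@dataclass(frozen=True)
class DomainHit:
    """One domain match on a protein (one row of a domain table)."""

    protein_id: str
    accession: str  # e.g. "PF00512"; may be empty if only a name is known
    name: str  # e.g. "HisKA"
    env_start: int  # aa, 1-based inclusive
    env_end: int  # aa, 1-based inclusive
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.env_start < 1:
            raise ValueError(f"env_start must be >= 1, got {self.env_start}")
        if self.env_end < self.env_start:
            raise ValueError(
                f"env_end {self.env_end} < env_start {self.env_start} "
                f"for {self.protein_id}/{self.name}"
            )
        if self.e_value < 0:
            raise ValueError(f"negative e-value for {self.protein_id}/{self.name}")

    @property
    def length(self) -> int:
        return self.env_end - self.env_start + 1

    @property
    def midpoint(self) -> float:
        return (self.env_start + self.env_end) / 2.0

    def overlap(self, other: "DomainHit") -> int:
        """Number of shared residues with another hit (0 if disjoint)."""
        return max(0, min(self.env_end, other.env_end) - max(self.env_start, other.env_start) + 1)


@dataclass
class ProteinArchitecture:
    """Overlap-resolved, ordered domain architecture of one protein.

    ``domains`` is sorted by ``env_start``; after resolution no pair of
    retained hits overlaps by more than the configured fraction of the
    shorter interval (see :func:`sigcensus.io.resolve_architecture`).
    """

    protein_id: str
    domains: list[DomainHit] = field(default_factory=list)
    length_aa: Optional[int] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        self.domains = sorted(self.domains, key=lambda h: (h.env_start, h.env_end))

    @property
    def domain_names(self) -> list[str]:
        return [h.name for h in self.domains]


@dataclass(frozen=True)
class GeneRecord:
    """One gene (coding or not) at a fixed position in the gene order.

    ``protein_id`` is ``None`` for pseudogenes/RNA genes; such records still
    occupy an ordinal, so they count as intervening genes in every
    neighborhood rule.
    """

    gene_id: str
    replicon_id: str
    ordinal: int
    start: int
    end: int
    strand: str  # "+" or "-"
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def is_coding(self) -> bool:
        return self.protein_id is not None


class Genome:
    """Ordered genes on one or more replicons, plus metadata.

    ``metadata`` keys used by the pipeline: ``ecotype`` (one of
    ``vent_specialist``, ``generalist``, ``host_associated``, ``unknown``),
    ``species``, ``genome_size``.
    """

    def __init__(
        self,
        genome_id: str,
        replicons: dict[str, list[GeneRecord]] | None = None,
        metadata: dict | None = None,
    ) -> None:
        self.genome_id = genome_id
        self.replicons: dict[str, list[GeneRecord]] = replicons or {}
        self.metadata: dict = metadata or {}
        self._validate()
        self._index()

    def _validate(self) -> None:
        seen: set[str] = set()
        for rep_id, genes in self.replicons.items():
            for i, g in enumerate(genes):
                if g.ordinal != i:
                    raise ValueError(
                        f"replicon {rep_id}: ordinal {g.ordinal} at position {i} "
                        "(ordinals must be 0-based and contiguous)"
                    )
                if g.gene_id in seen:
                    raise ValueError(f"duplicate gene_id {g.gene_id}")
                seen.add(g.gene_id)

    def _index(self) -> None:
        self._by_gene: dict[str, GeneRecord] = {}
        self._by_protein: dict[str, GeneRecord] = {}
        for genes in self.replicons.values():
            for g in genes:
                self._by_gene[g.gene_id] = g
                if g.protein_id is not None:
                    if g.protein_id in self._by_protein:
                        raise ValueError(f"protein_id {g.protein_id} on two genes")
                    self._by_protein[g.protein_id] = g

    # ------------------------------------------------------------------ access
    def genes(self) -> Iterable[GeneRecord]:
        for genes in self.replicons.values():
            yield from genes

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.replicons.values())

    def gene(self, gene_id: str) -> GeneRecord:
        return self._by_gene[gene_id]

    def gene_for_protein(self, protein_id: str) -> Optional[GeneRecord]:
        return self._by_protein.get(protein_id)

    @property
    def ecotype(self) -> str:
        return self.metadata.get("ecotype", "unknown")

    # --------------------------------------------------------------- distance
    def distance(self, gene_a: str, gene_b: str) -> float:
        """Number of intervening genes between two genes.

        Adjacent genes are at distance 0; a gene and itself at -1 by the
        formula, reported as 0; different replicons -> ``inf``.
        """
        a, b = self._by_gene[gene_a], self._by_gene[gene_b]
        if a.replicon_id != b.replicon_id:
            return INF
        return max(0, abs(a.ordinal - b.ordinal) - 1)

    # --------------------------------------------------------------- symmetry
    def reversed(self) -> "Genome":
        """Mirror every replicon: reverse gene order, flip strands.

        Coordinates are mirrored around each replicon's span so the result
        is again a valid genome.  Classifications, links, clusters and
        census rows must be invariant under this transform.
        """
        new_reps: dict[str, list[GeneRecord]] = {}
        for rep_id, genes in self.replicons.items():
            if not genes:
                new_reps[rep_id] = []
                continue
            span = max(g.end for g in genes) + min(g.start for g in genes)
            rev = []
            for i, g in enumerate(reversed(genes)):
                rev.append(
                    GeneRecord(
                        gene_id=g.gene_id,
                        replicon_id=rep_id,
                        ordinal=i,
                        start=span - g.end,
                        end=span - g.start,
                        strand="-" if g.strand == "+" else "+",
                        protein_id=g.protein_id,
                    )
                )
            new_reps[rep_id] = rev
        return Genome(self.genome_id, new_reps, dict(self.metadata))
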