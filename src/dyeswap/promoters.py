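"""Promoter extraction from a genome FASTA and gene annotation GFF.

For each gene, up to ``upstream_bp`` (default 1000) bases upstream of the
transcription start are taken, where the start is the upstream edge of an
annotated 5'UTR when one exists (so the 5'UTR itself is excluded) and the
gene's 5'-most coordinate otherwise. The window is truncated at the
nearest boundary of any other annotated gene on either strand and at the
contig edge; minus-strand promoters are reverse-complemented so every
output reads 5'->3' toward its gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
from pyfaidx import Fasta

from dyeswap.simulate import reverse_complement

TRUNC_NONE = "none"
TRUNC_NEIGHBOR = "neighbor_overlap"
TRUNC_CONTIG = "contig_start"

DEFAULT_UPSTREAM = 1000
DEFAULT_MIN_LENGTH = 20


@dataclass
class PromoterRecord:
    gene: str
    seq: str
    length: int
    truncation: str


@dataclass
class PromoterSet:
    records: dict[str, PromoterRecord]
    dropped: dict[str, str] = field(default_factory=dict)

    def sequences(self) -> dict[str, str]:
        return {g: r.seq for g, r in self.records.items()}

    def __len__(self) -> int:
        return len(self.records)


def _gene_id(feature: gffutils.Feature) -> str:
    for key in ("ID", "gene_id", "Name"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return feature.id


def extract_promoters(
    genome_fasta: str,
    annotation_gff: str,
    upstream_bp: int = DEFAULT_UPSTREAM,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> PromoterSet:
    """Extract non-overlapping upstream promoter sequences for every gene.

    GFF coordinates are 1-based inclusive. Genes absent from the genome
    sequence are skipped with a warning; promoters shorter than
    ``min_length`` after truncation are dropped with a record.
    """
    db = gffutils.create_db(
        annotation_gff,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genome = Fasta(genome_fasta, sequence_always_upper=True)

    genes = list(db.features_of_type("gene"))
    by_contig: dict[str, list[gffutils.Feature]] = {}
    for g in genes:
        by_contig.setdefault(g.seqid, []).append(g)

    records: dict[str, PromoterRecord] = {}
    dropped: dict[str, str] = {}
    for gene in genes:
        gid = _gene_id(gene)
        if gene.seqid not in genome:
            warnings.warn(f"gene {gid}: contig {gene.seqid} absent from genome; skipped", stacklevel=2)
            continue
        contig_len = len(genome[gene.seqid])
        utrs = list(db.children(gene, featuretype=("five_prime_UTR", "five_prime_utr")))
        others = [o for o in by_contig[gene.seqid] if o.id != gene.id]

        if gene.strand != "-":
            # anchor = first base of the transcript (5'UTR start when annotated)
            anchor = min([gene.start] + [u.start for u in utrs])
            start = anchor - upstream_bp
            end = anchor - 1
            reason = TRUNC_NONE
            # any gene body intruding into the window truncates it (an
            # overlap reaching the anchor empties the promoter entirely)
            bound = max(
                (min(o.end, anchor - 1) for o in others if o.start < anchor),
                default=None,
            )
            if bound is not None and bound + 1 > start:
                start, reason = bound + 1, TRUNC_NEIGHBOR
            if start < 1:
                start, reason = 1, TRUNC_CONTIG
            seq = str(genome[gene.seqid][start - 1 : end]) if end >= start else ""
        else:
            anchor = max([gene.end] + [u.end for u in utrs])
            start = anchor + 1
            end = anchor + upstream_bp
            reason = TRUNC_NONE
            bound = min(
                (max(o.start, anchor + 1) for o in others if o.end > anchor),
                default=None,
            )
            if bound is not None and bound - 1 < end:
                end, reason = bound - 1, TRUNC_NEIGHBOR
            if end > contig_len:
                end, reason = contig_len, TRUNC_CONTIG
            seq = reverse_complement(str(genome[gene.seqid][start - 1 : end])) if end >= start else ""

        if len(seq) < min_length:
            dropped[gid] = f"promoter length {len(seq)} < minimum {min_length}"
            continue
        records[gid] = PromoterRecord(gene=gid, seq=seq.upper(), length=len(seq), truncation=reason)
    return PromoterSet(records=records, dropped=dropped)
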