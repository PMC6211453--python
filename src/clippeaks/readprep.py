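"""Read preparation: filters, diagnostic-event extraction and per-gene count tensors.

CLIP-seq reads carry crosslink-induced artifacts ("diagnostic events"):
nucleotide conversions (e.g. T>C in PAR-CLIP), deletions (HITS-CLIP) and read
truncations (iCLIP/eCLIP).  This module turns aligned reads plus a gene
annotation into per-gene arrays of coverage and diagnostic-event counts, the
observed variables of the downstream probabilistic model.

Coordinates are 0-based half-open throughout; GTF input (1-based closed) is
converted on load.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: Diagnostic-event categories: 12 substitutions, 4 single-base deletions and
#: the two read ends (5' and 3' truncation signals).  The event tensor carries
#: one extra trailing slot for "read covers the position with no event".
SUBSTITUTIONS = tuple(f"{r}>{a}" for r in BASES for a in BASES if r != a)
DELETIONS = tuple(f"del_{b}" for b in BASES)
READ_ENDS = ("end5", "end3")
EVENT_CATEGORIES = SUBSTITUTIONS + DELETIONS + READ_ENDS
EVENT_INDEX = {name: i for i, name in enumerate(EVENT_CATEGORIES)}
N_EVENT_TYPES = len(EVENT_CATEGORIES)  # M = 18

#: Conversions this close to a read end are discarded as likely mis-mapping.
END_EXCLUSION = 2

SNP_MIN_READS = 20
SNP_MIN_FRAC = 0.20


@dataclass
class GeneModel:
    """A gene as a segmentation unit: span, exons and per-position masks."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)
    overlaps_other_gene_mask: np.ndarray | None = None
    mirna_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("empty gene span")
        if not self.exon_intervals:
            self.exon_intervals = [(self.start, self.end)]
        self.exon_intervals = sorted(self.exon_intervals)
        prev = self.start
        for s, e in self.exon_intervals:
            if s < self.start or e > self.end or s >= e:
                raise ValueError("exon outside gene span")
            if s < prev and (s, e) != self.exon_intervals[0]:
                raise ValueError("exons overlap")
            prev = e
        n = self.n_pos
        if self.overlaps_other_gene_mask is None:
            self.overlaps_other_gene_mask = np.zeros(n, dtype=bool)
        if self.mirna_mask is None:
            self.mirna_mask = np.zeros(n, dtype=bool)
        for name in ("overlaps_other_gene_mask", "mirna_mask"):
            m = getattr(self, name)
            if len(m) != n:
                raise ValueError(f"{name} length {len(m)} != span length {n}")

    @property
    def n_pos(self) -> int:
        return self.end - self.start


@dataclass
class AlignedRead:
    """Minimal alignment record: footprint, strand and reference differences.

    ``mismatches`` are (read_offset, genomic_pos, ref_base, alt_base);
    ``deletions`` are (genomic_pos, ref_base).  ``strand`` may be None when
    the aligner recorded no strand information.
    """

    chrom: str
    start: int
    end: int
    strand: str | None
    read_length: int
    mismatches: list[tuple[int, int, str, str]] = field(default_factory=list)
    deletions: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class SiteTensor:
    """Per-gene observed data: coverage and diagnostic-event counts.

    coverage: (n_pos, n_libraries) int array.
    events:   (n_pos, n_libraries, M+1) int array; slots 0..M-1 follow
              EVENT_CATEGORIES and the last slot counts covering reads with
              no event, so rows sum to coverage at unmasked positions.
    """

    gene_id: str
    n_pos: int
    coverage: np.ndarray
    events: np.ndarray
    library_roles: tuple[str, ...]
    snp_mask: np.ndarray
    mirna_mask: np.ndarray
    overlap_mask: np.ndarray

    @property
    def n_libraries(self) -> int:
        return self.coverage.shape[1]

    @property
    def clip_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.library_roles) if r == "CLIP"])

    @property
    def background_indices(self) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.library_roles) if r == "background"]
        )

    def apply_snp_mask(self, mask: np.ndarray) -> None:
        """Zero out event vectors (all slots) at SNP-like positions.

        Coverage is retained: SNP positions still inform the coverage model,
        they are only removed from diagnostic-event modelling.
        """
        mask = np.asarray(mask, dtype=bool)
        self.events[mask] = 0
        self.snp_mask = self.snp_mask | mask


def filter_read(read: AlignedRead, gene: GeneModel, max_mismatches: int = 2) -> bool:
    """Keep a read iff it has at most two mismatches and maps to the gene strand.

    Reads without strand information pass the strand test vacuously.
    """
    if len(read.mismatches) > max_mismatches:
        return False
    if read.strand is not None and read.strand != gene.strand:
        return False
    return True


def extract_diagnostic_events(read: AlignedRead) -> list[tuple[int, str]]:
    """List (genomic_pos, category) diagnostic events carried by a read.

    Conversions within the first or last two read bases are dropped (likely
    mis-mapped ends); deletions and the two read-end events are always kept.
    The 5' end is the leftmost aligned position on the + strand and the
    rightmost on the - strand.
    """
    events: list[tuple[int, str]] = []
    L = read.read_length
    for offset, pos, ref, alt in read.mismatches:
        if offset < END_EXCLUSION or offset >= L - END_EXCLUSION:
            continue
        key = f"{ref}>{alt}"
        if key in EVENT_INDEX:
            events.append((pos, key))
    for pos, ref in read.deletions:
        key = f"del_{ref}"
        if key in EVENT_INDEX:
            events.append((pos, key))
    left, right = read.start, read.end - 1
    if read.strand == "-":
        events.append((right, "end5"))
        events.append((left, "end3"))
    else:
        events.append((left, "end5"))
        events.append((right, "end3"))
    return events


def detect_snp_positions(
    background_tensor: SiteTensor,
    min_reads: int = SNP_MIN_READS,
    min_frac: float = SNP_MIN_FRAC,
) -> np.ndarray:
    """Flag positions whose background libraries look heterozygous/SNP-like.

    A position is flagged when the pooled background coverage is at least
    ``min_reads`` and at least ``min_frac`` of those reads carry a conversion
    (substitution) event.  Flagged positions are later excluded from
    diagnostic-event modelling so germline variants are not mistaken for
    crosslink signatures.
    """
    bg = background_tensor.background_indices
    if bg.size == 0:
        raise ValueError(
            "SNP masking requires at least one background library; none present"
        )
    cov = background_tensor.coverage[:, bg].sum(axis=1)
    n_sub = len(SUBSTITUTIONS)
    conv = background_tensor.events[:, bg, :n_sub].sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(cov > 0, conv / np.maximum(cov, 1), 0.0)
    return (cov >= min_reads) & (frac >= min_frac)


def build_site_tensor(
    reads_per_library: list[list[AlignedRead]],
    gene: GeneModel,
    library_roles: list[str] | tuple[str, ...],
    snp_mask: np.ndarray | None = None,
) -> SiteTensor:
    """Aggregate filtered reads into the per-gene coverage/event tensor.

    Coverage counts full read footprints clipped to the gene span.  Event
    counts come from :func:`extract_diagnostic_events`.  SNP-masked positions
    keep their coverage but contribute no event counts; miRNA-masked
    positions are zeroed entirely, as if never sequenced.
    """
    if len(reads_per_library) != len(library_roles):
        raise ValueError("one role per library required")
    for role in library_roles:
        if role not in ("CLIP", "background"):
            raise ValueError(f"unknown library role {role!r}")
    n_pos = gene.n_pos
    n_lib = len(reads_per_library)
    coverage = np.zeros((n_pos, n_lib), dtype=np.int64)
    events = np.zeros((n_pos, n_lib, N_EVENT_TYPES + 1), dtype=np.int64)
    n_skipped = 0
    for w, reads in enumerate(reads_per_library):
        diff = np.zeros(n_pos + 1, dtype=np.int64)
        ev_pos: list[int] = []
        ev_cat: list[int] = []
        for read in reads:
            s = read.start - gene.start
            e = read.end - gene.start
            if e <= 0 or s >= n_pos:
                n_skipped += 1
                continue
            diff[max(s, 0)] += 1
            diff[min(e, n_pos)] -= 1
            for pos, cat in extract_diagnostic_events(read):
                p = pos - gene.start
                if 0 <= p < n_pos:
                    ev_pos.append(p)
                    ev_cat.append(EVENT_INDEX[cat])
        coverage[:, w] = np.cumsum(diff[:-1])
        if ev_pos:
            np.add.at(events[:, w, :], (np.array(ev_pos), np.array(ev_cat)), 1)
    if n_skipped:
        logger.warning(
            "%s: skipped %d reads outside the gene span", gene.gene_id, n_skipped
        )
    # "no event" slot completes each row to the coverage total
    ev_sum = events[:, :, :N_EVENT_TYPES].sum(axis=2)
    events[:, :, N_EVENT_TYPES] = np.maximum(coverage - ev_sum, 0)
    tensor = SiteTensor(
        gene_id=gene.gene_id,
        n_pos=n_pos,
        coverage=coverage,
        events=events,
        library_roles=tuple(library_roles),
        snp_mask=np.zeros(n_pos, dtype=bool),
        mirna_mask=np.asarray(gene.mirna_mask, dtype=bool).copy(),
        overlap_mask=np.asarray(gene.overlaps_other_gene_mask, dtype=bool).copy(),
    )
    if tensor.mirna_mask.any():
        tensor.coverage[tensor.mirna_mask] = 0
        tensor.events[tensor.mirna_mask] = 0
    if snp_mask is not None:
        tensor.apply_snp_mask(snp_mask)
    return tensor


# ---------------------------------------------------------------------------
# Annotation and alignment I/O
# ---------------------------------------------------------------------------


def load_genes_gtf(path: str, mirna_path: str | None = None) -> list[GeneModel]:
    """Load gene models from a GTF/GFF file.

    Gene spans come from ``gene`` records (or are inferred as the union of a
    gene's exons), exon structure from ``exon`` records.  Positions covered by
    two or more genes on either strand are marked in
    ``overlaps_other_gene_mask``; an optional miRNA annotation (BED or GTF)
    fills ``mirna_mask``.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes.get("gene_id", [ex.id])[0]
        exons_by_gene.setdefault(gid, []).append((ex.start - 1, ex.end))
    gene_feats = list(db.features_of_type("gene"))
    if not gene_feats:
        raise ValueError(f"no gene records found in {path}")
    for gf in gene_feats:
        gid = gf.attributes.get("gene_id", [gf.id])[0]
        start, end = gf.start - 1, gf.end
        exons = exons_by_gene.get(gid, [(start, end)])
        exons = _merge_intervals(exons)
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=gf.seqid,
                strand=gf.strand if gf.strand in "+-" else "+",
                start=start,
                end=end,
                exon_intervals=exons,
            )
        )
    _fill_overlap_masks(genes)
    if mirna_path is not None:
        apply_mirna_annotation(genes, mirna_path)
    return genes


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _fill_overlap_masks(genes: list[GeneModel]) -> None:
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    for g in genes:
        mask = np.zeros(g.n_pos, dtype=bool)
        for iv in trees[g.chrom].overlap(g.start, g.end):
            if iv.data == g.gene_id:
                continue
            lo = max(iv.begin, g.start) - g.start
            hi = min(iv.end, g.end) - g.start
            mask[lo:hi] = True
        g.overlaps_other_gene_mask = mask


def apply_mirna_annotation(genes: list[GeneModel], path: str) -> None:
    """Mark gene positions overlapping annotated miRNA genes (BED or GTF)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 9 and parts[3].isdigit() and parts[4].isdigit():
                intervals.append((parts[0], int(parts[3]) - 1, int(parts[4])))  # GTF
            else:
                intervals.append((parts[0], int(parts[1]), int(parts[2])))  # BED
    for g in genes:
        for chrom, s, e in intervals:
            if chrom != g.chrom or e <= g.start or s >= g.end:
                continue
            lo = max(s, g.start) - g.start
            hi = min(e, g.end) - g.start
            g.mirna_mask[lo:hi] = True


def save_tensors(tensors: list[SiteTensor], path: str) -> None:
    """Serialize tensors to one compressed .npz archive for resumable runs.

    Layout: per gene ``<i>.coverage``, ``<i>.events`` and a packed mask
    array (rows: snp, mirna, overlap), plus global gene ids and roles.
    """
    payload: dict[str, np.ndarray] = {
        "gene_ids": np.array([t.gene_id for t in tensors]),
        "library_roles": np.array(tensors[0].library_roles),
    }
    for i, t in enumerate(tensors):
        payload[f"{i}.coverage"] = t.coverage
        payload[f"{i}.events"] = t.events
        payload[f"{i}.masks"] = np.stack(
            [t.snp_mask, t.mirna_mask, t.overlap_mask]
        )
    np.savez_compressed(path, **payload)


def load_tensors(path: str) -> list[SiteTensor]:
    """Inverse of :func:`save_tensors`."""
    with np.load(path, allow_pickle=False) as data:
        gene_ids = [str(g) for g in data["gene_ids"]]
        roles = tuple(str(r) for r in data["library_roles"])
        out = []
        for i, gid in enumerate(gene_ids):
            cov = data[f"{i}.coverage"]
            masks = data[f"{i}.masks"]
            out.append(
                SiteTensor(
                    gene_id=gid,
                    n_pos=cov.shape[0],
                    coverage=cov,
                    events=data[f"{i}.events"],
                    library_roles=roles,
                    snp_mask=masks[0],
                    mirna_mask=masks[1],
                    overlap_mask=masks[2],
                )
            )
    return out


def read_from_alignment(aln) -> AlignedRead | None:
    """Convert a pysam AlignedSegment to an :class:`AlignedRead`.

    Requires the MD tag (standard for most aligners) to recover mismatch
    reference bases; returns None for unmapped or MD-less records.
    """
    if aln.is_unmapped:
        return None
    try:
        pairs = aln.get_aligned_pairs(with_seq=True)
    except ValueError:
        return None
    seq = aln.query_sequence or ""
    mismatches: list[tuple[int, int, str, str]] = []
    deletions: list[tuple[int, str]] = []
    for qpos, rpos, ref in pairs:
        if rpos is None or ref is None:
            continue
        if qpos is None:
            deletions.append((rpos, ref.upper()))
        elif ref.islower():
            alt = seq[qpos].upper() if qpos < len(seq) else "N"
            mismatches.append((qpos, rpos, ref.upper(), alt))
    return AlignedRead(
        chrom=aln.reference_name,
        start=aln.reference_start,
        end=aln.reference_end,
        strand="-" if aln.is_reverse else "+",
        read_length=aln.query_length or aln.infer_query_length() or 0,
        mismatches=mismatches,
        deletions=deletions,
    )


def load_reads_sam(
    path: str, genes: list[GeneModel], min_mapq: int = 0
) -> dict[str, list[AlignedRead]]:
    """Read a SAM/BAM file and assign reads to overlapping genes.

    A read overlapping several genes is assigned to each of them (the model
    treats genes independently).  ``min_mapq`` optionally drops low-quality
    alignments (multi-mapper policy belongs to the upstream aligner; the
    floor is a coarse knob on top of it).  Reads are NOT yet filtered; apply
    :func:`filter_read` per gene afterwards.
    """
    import pysam
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    out: dict[str, list[AlignedRead]] = {g.gene_id: [] for g in genes}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for aln in fh:
                if min_mapq and aln.mapping_quality < min_mapq:
                    continue
                read = read_from_alignment(aln)
                if read is None or read.chrom not in trees:
                    continue
                for iv in trees[read.chrom].overlap(read.start, read.end):
                    out[iv.data].append(read)
    return out


def build_tensors(
    reads_by_gene_per_library: list[dict[str, list[AlignedRead]]],
    genes: list[GeneModel],
    library_roles: list[str],
    mask_snps: bool = True,
    max_mismatches: int = 2,
    snp_min_reads: int = SNP_MIN_READS,
    snp_min_frac: float = SNP_MIN_FRAC,
) -> list[SiteTensor]:
    """Filter reads, build tensors and apply SNP masking for every gene."""
    tensors = []
    for gene in genes:
        per_lib = []
        for lib in reads_by_gene_per_library:
            reads = [
                r
                for r in lib.get(gene.gene_id, [])
                if filter_read(r, gene, max_mismatches)
            ]
            per_lib.append(reads)
        tensors.append(build_site_tensor(per_lib, gene, library_roles))
    if mask_snps and "background" in library_roles:
        for t in tensors:
            t.apply_snp_mask(
                detect_snp_positions(t, snp_min_reads, snp_min_frac)
            )
    return tensors
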