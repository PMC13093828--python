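"""5' RACE read processing and transcription start site (TSS) calling.

Implements the "traditional" RACE read structure: cDNA is synthesised from a
gene-specific primer, poly-dA tailed, and amplified from an anchor (QT)
primer that pairs with the tail.  A sequencing read in the anchor
orientation therefore reads: anchor, a poly-T run, then the sense-strand
sequence of the transcript starting at its 5' end.  The pipeline

  1. keeps reads carrying at least the terminal ``min_terminal_match`` bases
     of the anchor (exact match),
  2. strips the maximal homopolymer tail run at the junction,
  3. aligns the remaining insert to the locus by exhaustive both-strand
     scan (unique best hit, bounded mismatches),
  4. tallies 5'-end positions relative to the main start codon in the
     no-zero c. convention,
  5. normalises counts across samples (TMM scale factors + CPM) and reports
     log10 percentages per sample,

plus the exact integer arithmetic for template-switching fragment sizes and
convergent-transcript 3'-end overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "RaceRead",
    "AnchoredInsert",
    "LocusAlignment",
    "TssTable",
    "NormalizedMatrix",
    "FragmentObservation",
    "ThreePrimeEnd",
    "read_fastq",
    "read_locus_fasta",
    "identify_anchored_reads",
    "strip_tail",
    "align_insert",
    "call_tss",
    "process_sample",
    "tmm_factors",
    "cpm_log10pct",
    "fragment_to_5prime",
    "extension_into_neighbor",
    "transcript_overlap",
]


@dataclass(frozen=True)
class RaceRead:
    read_id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty read sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.read_id}: bad characters {sorted(bad)}")


@dataclass(frozen=True)
class AnchoredInsert:
    read_id: str
    insert_seq: str
    tail_len: int
    anchor_match_len: int


@dataclass(frozen=True)
class LocusAlignment:
    """Placement of a stripped insert on the locus.

    ``five_prime_pos`` is the 0-based locus coordinate of the base adjacent
    to the tail junction (the transcript's 5' end); conversion to the c.
    convention happens in :func:`call_tss`.
    """

    read_id: str
    five_prime_pos: int
    strand: str  # "sense" | "antisense"
    mismatches: int


def read_fastq(path: str | Path) -> list[RaceRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(RaceRead(rec.id, str(rec.seq).upper(), qual))
    return reads


def read_locus_fasta(path: str | Path) -> str:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 1:
        raise ValueError(f"expected a single-record locus FASTA, got {len(recs)}")
    return str(recs[0].seq).upper()


def identify_anchored_reads(
    read: RaceRead, anchor_seq: str, min_terminal_match: int = 8
) -> AnchoredInsert | None:
    """Keep the read iff it contains the anchor's terminal bases exactly.

    The longest matching anchor suffix (length >= ``min_terminal_match``) is
    located and everything up to and including it is removed; the remainder
    (tail + insert) is returned.  ``None`` signals rejection.
    """
    if len(anchor_seq) < min_terminal_match:
        raise ValueError("anchor shorter than min_terminal_match")
    for match_len in range(len(anchor_seq), min_terminal_match - 1, -1):
        suffix = anchor_seq[-match_len:]
        i = read.seq.find(suffix)
        if i >= 0:
            return AnchoredInsert(
                read_id=read.read_id,
                insert_seq=read.seq[i + match_len :],
                tail_len=0,
                anchor_match_len=match_len,
            )
    return None


def strip_tail(
    anchored: AnchoredInsert, tail_base: str = "T", min_run: int = 5
) -> AnchoredInsert | None:
    """Remove the homopolymer tail run at the anchor side of the insert.

    The first non-tail base defines the transcript 5' end downstream.  Runs
    shorter than ``min_run`` leave the junction ambiguous -> rejection.
    """
    if tail_base not in ("A", "T"):
        raise ValueError("tail_base must be A or T")
    seq = anchored.insert_seq
    run = 0
    while run < len(seq) and seq[run] == tail_base:
        run += 1
    if run < min_run:
        return None
    return replace(anchored, insert_seq=seq[run:], tail_len=run)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def align_insert(
    insert: str,
    locus_seq: str,
    max_mismatch: int = 1,
    min_len: int = 20,
    read_id: str = "",
) -> LocusAlignment | None:
    """Exhaustive both-strand scan of the locus for the unique best hit.

    Returns ``None`` for short inserts, hits exceeding ``max_mismatch``, or
    ties (ambiguous placement); raises if the locus is shorter than the
    insert.  Ns in the insert count as mismatches.
    """
    m = len(insert)
    if m > len(locus_seq):
        raise ValueError("locus shorter than insert")
    if m < min_len:
        return None
    locus_arr = _encode(locus_seq)
    windows = np.lib.stride_tricks.sliding_window_view(locus_arr, m)
    mism_sense = (windows != _encode(insert)).sum(axis=1)
    mism_anti = (windows != _encode(_revcomp(insert))).sum(axis=1)
    best = min(mism_sense.min(), mism_anti.min())
    if best > max_mismatch:
        return None
    hits_sense = np.flatnonzero(mism_sense == best)
    hits_anti = np.flatnonzero(mism_anti == best)
    if len(hits_sense) + len(hits_anti) != 1:
        return None  # ambiguous
    if len(hits_sense) == 1:
        off = int(hits_sense[0])
        return LocusAlignment(read_id, off, "sense", int(best))
    off = int(hits_anti[0])
    # insert matched the reverse strand: the junction-adjacent base maps to
    # the rightmost locus position of the window
    return LocusAlignment(read_id, off + m - 1, "antisense", int(best))


def _locus_to_c(locus_pos: int, orf_start: int) -> int:
    diff = locus_pos - orf_start
    return diff if diff < 0 else diff + 1


@dataclass
class TssTable:
    """Per-sample counts of transcript 5'-end positions (c. convention)."""

    sample_ids: list[str]
    counts: dict[int, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        idx = sorted(self.counts)
        data = np.array([self.counts[p] for p in idx], dtype=int).reshape(
            len(idx), len(self.sample_ids)
        )
        return pd.DataFrame(data, index=pd.Index(idx, name="position"),
                            columns=self.sample_ids)

    @classmethod
    def merge(cls, tables: list["TssTable"]) -> "TssTable":
        sample_ids = [s for t in tables for s in t.sample_ids]
        positions = sorted({p for t in tables for p in t.counts})
        counts = {}
        for p in positions:
            row = []
            for t in tables:
                c = t.counts.get(p)
                row.extend(c if c is not None else [0] * len(t.sample_ids))
            counts[p] = np.array(row, dtype=int)
        return cls(sample_ids=sample_ids, counts=counts)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def write_bed(self, path: str | Path, locus_name: str, orf_start: int) -> None:
        """BED6 rows (0-based half-open), one per (position, sample)."""
        with open(path, "w") as fh:
            for pos in sorted(self.counts):
                locus_pos = orf_start + (pos if pos < 0 else pos - 1)
                for sample, n in zip(self.sample_ids, self.counts[pos]):
                    if n > 0:
                        fh.write(
                            f"{locus_name}\t{locus_pos}\t{locus_pos + 1}\t"
                            f"{sample}:TSS{pos}\t{int(n)}\t+\n"
                        )


def call_tss(
    alignments: list[LocusAlignment], orf_start_in_locus: int, sample_id: str
) -> TssTable:
    """Tally 5'-end positions relative to the start codon for one sample.

    Only sense-strand alignments are counted (the gene under study is on
    the sense strand of the supplied locus); each contributes one count at
    its c. position (upstream negative, no zero).
    """
    counter: dict[int, int] = {}
    for aln in alignments:
        if aln.strand != "sense":
            continue
        pos = _locus_to_c(aln.five_prime_pos, orf_start_in_locus)
        counter[pos] = counter.get(pos, 0) + 1
    return TssTable(
        sample_ids=[sample_id],
        counts={p: np.array([n]) for p, n in counter.items()},
    )


def process_sample(
    reads: list[RaceRead],
    anchor_seq: str,
    locus_seq: str,
    orf_start_in_locus: int,
    sample_id: str,
    min_terminal_match: int = 8,
    tail_base: str = "T",
    min_run: int = 5,
    max_mismatch: int = 1,
    min_len: int = 20,
) -> tuple[TssTable, dict[str, int]]:
    """Full anchor -> tail -> align -> tally chain with a QC tally."""
    qc = {"total": len(reads), "no_anchor": 0, "short_tail": 0,
          "unaligned": 0, "antisense": 0, "counted": 0}
    alignments = []
    for read in reads:
        anchored = identify_anchored_reads(read, anchor_seq, min_terminal_match)
        if anchored is None:
            qc["no_anchor"] += 1
            continue
        stripped = strip_tail(anchored, tail_base, min_run)
        if stripped is None:
            qc["short_tail"] += 1
            continue
        aln = align_insert(stripped.insert_seq, locus_seq, max_mismatch,
                           min_len, read_id=read.read_id)
        if aln is None:
            qc["unaligned"] += 1
            continue
        if aln.strand != "sense":
            qc["antisense"] += 1
            continue
        qc["counted"] += 1
        alignments.append(aln)
    return call_tss(alignments, orf_start_in_locus, sample_id), qc


# --- between-sample normalisation -------------------------------------------

def tmm_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors, one per sample (column).

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those; per sample the factor is 2 to the
    inverse-variance-weighted mean of M values after trimming 30% of M and
    5% of A from each tail (rows zero in either sample excluded).  Factors
    are rescaled to geometric mean 1.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a positions x samples matrix with >= 2 samples")
    if (x < 0).any() or not np.isfinite(x).all():
        raise ValueError("counts must be finite and non-negative")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample")
    f75 = np.quantile(x, 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [_tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref]) for j in range(x.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    from scipy.stats import rankdata

    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / n_obs) / (ref / n_ref))
        a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
        w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[fin], a[fin], w[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f)


@dataclass
class NormalizedMatrix:
    """log10 of TMM-scaled count percentages (zero counts are missing)."""

    values: pd.DataFrame
    tmm_factors: np.ndarray


def cpm_log10pct(
    counts: pd.DataFrame, factors: np.ndarray | None = None
) -> NormalizedMatrix:
    """Scale counts by effective library size, then log10 percentages.

    scaled = count / (library_size * factor); per-sample percentages sum to
    100 over non-missing cells; zeros are reported as NaN rather than -inf.
    """
    if factors is None:
        factors = tmm_factors(counts)
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    scaled = x / (lib * factors)
    pct = 100.0 * scaled / scaled.sum(axis=0)
    vals = np.full_like(pct, np.nan)
    np.log10(pct, out=vals, where=x > 0)
    df = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    return NormalizedMatrix(values=df, tmm_factors=np.asarray(factors))


# --- 5'/3' end arithmetic ----------------------------------------------------

@dataclass(frozen=True)
class FragmentObservation:
    """A template-switching RACE fragment size observed on a gel."""

    fragment_len: int
    primer_pos: int  # transcript coordinate of the gene-specific primer 3' end
    tso_len: int = 36

    def __post_init__(self) -> None:
        if self.primer_pos < 1:
            raise ValueError("primer_pos must be >= 1 (downstream of c.1)")
        if self.fragment_len <= self.tso_len:
            raise ValueError("fragment does not extend past the TSO")


@dataclass(frozen=True)
class ThreePrimeEnd:
    """3' end of a transcript relative to its gene's stop codon."""

    ext_past_stop: int
    intergenic_len: int = 51

    def __post_init__(self) -> None:
        if self.ext_past_stop < 0 or self.intergenic_len < 0:
            raise ValueError("lengths must be non-negative")


def fragment_to_5prime(obs: FragmentObservation) -> int:
    """Infer the 5'-end c. coordinate from a fragment length.

    The insert upstream of the primer is fragment_len - tso_len; a 5' end
    exactly at the A of the start codon is reported as +1 (no c.0).
    """
    offset = obs.fragment_len - obs.tso_len - obs.primer_pos
    return -offset if offset > 0 else 1 - offset


def extension_into_neighbor(end: ThreePrimeEnd) -> int:
    """Bases by which a 3' extension reaches into the convergent ORF."""
    return max(0, end.ext_past_stop - end.intergenic_len)


def transcript_overlap(ext_a: int, ext_b: int, intergenic_len: int) -> int:
    """Overlap of two convergent transcripts whose stops are intergenic_len apart."""
    if ext_a < 0 or ext_b < 0 or intergenic_len < 0:
        raise ValueError("inputs must be non-negative")
    return max(0, ext_a + ext_b - intergenic_len)
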