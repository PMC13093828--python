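"""Seeded generators for every input the pipeline consumes, with truth.

Each generator is a pure function of its spec and seed (byte-identical
reruns) and returns a :class:`TruthRecord` carrying the planted ground
truth, so downstream stages can be scored without consulting anything else.

Defaults encode the study conditions the package targets: a 15-dataset
microarray-style compendium with a 30-gene co-regulated module (query
included) planted in 5 datasets at a 3.0 log2 effect over 0.5 log2 noise; a
convergent two-gene locus whose 5' leader carries uORFs at -27, -66, -80,
-96 and -180 with their published stop-codon structure; "traditional"
5' RACE reads (35-nt QT-style anchor + variable poly-T tail + sense-strand
insert) drawn from a TSS mixture over -24/-29/-32/-39; and qPCR Ct tables
with known fold changes.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .expression_screen import ExpressionDataset, write_expression_matrix
from .quant_stats import CtTable
from .race_tss import RaceRead
from .uorf_annotate import STOP_CODONS, LocusModel

__all__ = [
    "TruthRecord",
    "CompendiumSpec",
    "LocusSpec",
    "ReadSpec",
    "QpcrSpec",
    "SyntheticLocus",
    "QT_ANCHOR",
    "make_compendium",
    "make_locus",
    "make_race_reads",
    "make_qpcr",
]

_BASES = np.array(list("ACGT"))

# 35-base anchor portion of a QT-style RACE primer (the poly-dT follows it)
QT_ANCHOR = "CGACTGGACCTGGTTCGTACGGATCCGAGCTCAAC"


@dataclass
class TruthRecord:
    """Ground truth serialised alongside every generated artifact."""

    generator: str
    spec: dict
    truth: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(**d)


def _spec_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


# --- expression compendium ---------------------------------------------------

@dataclass
class CompendiumSpec:
    """A multi-dataset expression compendium with a planted module."""

    seed: int
    n_datasets: int = 15
    n_genes: int = 4500
    n_conditions: int = 8
    module_size: int = 30
    query_gene: str = "YJL059W"
    housekeeping_genes: tuple[str, ...] = ("YFL039C", "YER178W")
    module_effect: float = 3.0
    module_datasets: tuple[int, ...] | None = None  # default: first 5 (or fewer)
    housekeeping_sd: float = 0.05
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.module_datasets is None:
            self.module_datasets = tuple(range(min(5, self.n_datasets)))
        if self.module_effect < 0 or self.noise_sd < 0 or self.housekeeping_sd < 0:
            raise ValueError("effect and noise sds must be non-negative")
        if self.module_size < 1:
            raise ValueError("module must contain at least the query gene")
        if any(not 0 <= d < self.n_datasets for d in self.module_datasets):
            raise ValueError("module_datasets index out of range")
        n_named = self.module_size + len(self.housekeeping_genes)
        if self.n_genes < n_named:
            raise ValueError("n_genes too small for module + housekeeping genes")


def make_compendium(
    spec: CompendiumSpec, out_dir: str | Path | None = None
) -> tuple[list[ExpressionDataset], TruthRecord]:
    """Generate one log2-ratio TSV-shaped dataset per compendium entry.

    Module genes (query included) share a planted 0/1 stress pattern scaled
    by ``module_effect`` in the module datasets; housekeeping rows are
    near-constant; everything rides on Gaussian log2 noise.
    """
    rng = np.random.default_rng(spec.seed)
    module = [spec.query_gene] + [
        f"YSYN{i:04d}W" for i in range(1, spec.module_size)
    ]
    n_bg = spec.n_genes - spec.module_size - len(spec.housekeeping_genes)
    background = [f"YBKG{i:04d}W" for i in range(n_bg)]
    gene_ids = module + list(spec.housekeeping_genes) + background
    order = rng.permutation(len(gene_ids))
    gene_ids = [gene_ids[i] for i in order]
    is_module = np.array([g in set(module) for g in gene_ids])
    is_hk = np.array([g in set(spec.housekeeping_genes) for g in gene_ids])

    labels = ["control"] + [f"cond{j}" for j in range(1, spec.n_conditions)]
    datasets = []
    patterns = {}
    for d in range(spec.n_datasets):
        noise = rng.normal(0.0, spec.noise_sd,
                           size=(spec.n_genes, spec.n_conditions))
        noise[is_hk] = rng.normal(0.0, spec.housekeeping_sd,
                                  size=(is_hk.sum(), spec.n_conditions))
        values = noise
        if d in spec.module_datasets:
            # stressed conditions share the module shift; control stays flat
            pattern = np.zeros(spec.n_conditions)
            on = rng.choice(np.arange(1, spec.n_conditions),
                            size=max(2, (spec.n_conditions - 1) // 2),
                            replace=False)
            pattern[np.sort(on)] = 1.0
            patterns[d] = pattern.tolist()
            values = values + np.where(is_module[:, None],
                                       spec.module_effect * pattern[None, :], 0.0)
        datasets.append(
            ExpressionDataset(
                dataset_id=f"ds{d:02d}",
                gene_ids=list(gene_ids),
                condition_labels=list(labels),
                control_index=0,
                values=values,
                missing=np.zeros_like(values, dtype=bool),
            )
        )
    truth = TruthRecord(
        generator="make_compendium",
        spec=_spec_dict(spec),
        truth={
            "module_genes": module,
            "module_datasets": [f"ds{d:02d}" for d in spec.module_datasets],
            "stress_patterns": {f"ds{d:02d}": p for d, p in patterns.items()},
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for ds in datasets:
            write_expression_matrix(ds, out_dir / f"{ds.dataset_id}.tsv")
        truth.to_json(out_dir / "truth.json")
    return datasets, truth


# --- convergent locus with planted uORFs -------------------------------------

_DEFAULT_UORF_STOPS: dict[int, tuple[tuple[int, str], ...]] = {
    -27: ((-18, "TAG"), (-9, "TAA"), (-3, "TAA")),
    -66: ((-60, "TGA"), (-45, "TAG"), (-30, "TAA")),
    # the ATG at -27 plus the A at the -24 TSS force a third frame stop at -26
    -80: ((-71, "TAG"), (-68, "TAA"), (-26, "TGA")),
    -96: (),
    -180: ((-168, "TAA"), (-162, "TAA")),
}

# junction bases at the planted transcription start sites (non-T so a poly-T
# tail cannot absorb the first transcribed base)
_DEFAULT_TSS_BASES = {-24: "A", -29: "A", -32: "C", -39: "A"}


@dataclass
class LocusSpec:
    """A two-gene convergent locus with planted uORFs and stop codons."""

    seed: int
    upstream_len: int = 250
    window: int = 192
    uorf_positions: tuple[int, ...] = (-180, -96, -80, -66, -27)
    uorf_stops: dict[int, tuple[tuple[int, str], ...]] = field(
        default_factory=lambda: dict(_DEFAULT_UORF_STOPS)
    )
    tss_bases: dict[int, str] = field(
        default_factory=lambda: dict(_DEFAULT_TSS_BASES)
    )
    main_orf_len: int = 300
    intergenic_len: int = 51
    convergent_orf_len: int = 300

    def __post_init__(self) -> None:
        if self.window > self.upstream_len:
            raise ValueError("window exceeds upstream length")
        for p in self.uorf_positions:
            if not -self.upstream_len <= p <= -3:
                raise ValueError(f"uORF position {p} outside the upstream region")
        for orf_len in (self.main_orf_len, self.convergent_orf_len):
            if orf_len % 3 or orf_len < 9:
                raise ValueError("ORF lengths must be multiples of 3, >= 9")


@dataclass
class SyntheticLocus:
    upstream_seq: str
    main_orf_seq: str
    intergenic_seq: str
    convergent_orf_seq: str  # in its own gene's reading orientation
    window: int = 192

    @property
    def orf_start(self) -> int:
        """0-based index of the main ORF's A in :attr:`locus_seq`."""
        return len(self.upstream_seq)

    @property
    def locus_seq(self) -> str:
        return (
            self.upstream_seq
            + self.main_orf_seq
            + self.intergenic_seq
            + str(Seq(self.convergent_orf_seq).reverse_complement())
        )

    def locus_model(self) -> LocusModel:
        return LocusModel(
            upstream_seq=self.upstream_seq,
            main_orf_seq=self.main_orf_seq,
            window=self.window,
        )

    def write_fasta(self, path: str | Path, name: str = "synthetic_locus") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f">{name} orf_start={self.orf_start}\n")
            seq = self.locus_seq
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _protect(protected: dict[int, str], idx: int, base: str) -> None:
    if protected.get(idx, base) != base:
        raise ValueError(
            f"infeasible locus spec: index {idx} needs both "
            f"{protected[idx]!r} and {base!r}"
        )
    protected[idx] = base


def _upstream_violations(
    seq: list[str], spec: LocusSpec, planted_stop_pos: set[int]
) -> list[tuple[int, int, int]]:
    """Triplet index ranges violating the planted uORF/stop structure."""
    ln = len(seq)
    bad = []
    uorfs = set(spec.uorf_positions)
    for n in range(3, spec.window + 1):
        i = ln - n
        if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G" and -n not in uorfs:
            bad.append((i, i + 1, i + 2))
    for start in spec.uorf_positions:
        for p in range(start + 3, -2, 3):
            if p > -3:
                break
            i = ln + p
            codon = "".join(seq[i : i + 3])
            if codon in STOP_CODONS and p not in planted_stop_pos:
                bad.append((i, i + 1, i + 2))
    return bad


def make_locus(
    spec: LocusSpec, out_fasta: str | Path | None = None
) -> tuple[SyntheticLocus, TruthRecord]:
    """Random locus with ATGs and stop codons planted exactly as specified.

    Background ATGs inside the scan window and unplanted stop codons in any
    planted uORF's frame are removed by rejection resampling, so the
    planted annotation is exact by construction.
    """
    rng = np.random.default_rng(spec.seed)
    ln = spec.upstream_len
    protected: dict[int, str] = {}
    for pos in spec.uorf_positions:
        for off, base in enumerate("ATG"):
            _protect(protected, ln + pos + off, base)
    planted_stop_pos: set[int] = set()
    for stops in spec.uorf_stops.values():
        for p, codon in stops:
            if codon not in STOP_CODONS:
                raise ValueError(f"{codon!r} is not a stop codon")
            planted_stop_pos.add(p)
            for off, base in enumerate(codon):
                _protect(protected, ln + p + off, base)
    for p, base in spec.tss_bases.items():
        _protect(protected, ln + p, base)

    seq = list(rng.choice(_BASES, size=ln))
    for idx, base in protected.items():
        seq[idx] = base
    for _ in range(20000):
        bad = _upstream_violations(seq, spec, planted_stop_pos)
        if not bad:
            break
        tri = bad[0]
        free = [i for i in tri if i not in protected]
        if not free:
            raise ValueError("infeasible locus spec: protected motifs collide")
        i = free[int(rng.integers(len(free)))]
        others = [b for b in "ACGT" if b != seq[i]]
        seq[i] = others[int(rng.integers(3))]
    else:
        raise RuntimeError("locus repair did not converge")

    def orf(length: int) -> str:
        non_stop = [c for c in
                    ("".join(t) for t in itertools.product("ACGT", repeat=3))
                    if c not in STOP_CODONS and c != "ATG"]
        inner = rng.choice(non_stop, size=length // 3 - 2)
        return "ATG" + "".join(inner) + "TAA"

    locus = SyntheticLocus(
        upstream_seq="".join(seq),
        main_orf_seq=orf(spec.main_orf_len),
        intergenic_seq="".join(rng.choice(_BASES, size=spec.intergenic_len)),
        convergent_orf_seq=orf(spec.convergent_orf_len),
        window=spec.window,
    )
    truth_uorfs = []
    for pos in sorted(spec.uorf_positions):
        frame_stops = sorted(
            p for p in planted_stop_pos if (p - pos) % 3 == 0 and pos < p <= -3
        )
        truth_uorfs.append(
            {
                "start_pos": pos,
                "frame": "in_frame" if pos % 3 == 0 else "out_of_frame",
                "stops": frame_stops,
            }
        )
    truth = TruthRecord(
        generator="make_locus",
        spec={**_spec_dict(spec),
              "uorf_stops": {str(k): list(map(list, v))
                             for k, v in spec.uorf_stops.items()},
              "tss_bases": {str(k): v for k, v in spec.tss_bases.items()}},
        truth={
            "uorfs": truth_uorfs,
            "knockout_edits": [f"c.{p + 1}T>A" for p in sorted(spec.uorf_positions)],
            "orf_start": locus.orf_start,
        },
    )
    if out_fasta is not None:
        locus.write_fasta(out_fasta)
        truth.to_json(Path(out_fasta).with_suffix(".truth.json"))
    return locus, truth


# --- 5' RACE reads -----------------------------------------------------------

@dataclass
class ReadSpec:
    """Traditional 5' RACE reads from a known TSS mixture."""

    seed: int
    tss_mixture: dict[int, float] = field(
        default_factory=lambda: {-24: 0.35, -29: 0.20, -32: 0.25, -39: 0.20}
    )
    n_reads: int = 20000
    read_len: int = 100
    anchor_seq: str = QT_ANCHOR
    tail_len_range: tuple[int, int] = (5, 30)
    substitution_rate: float = 0.0
    primer_pos: int = 99

    def __post_init__(self) -> None:
        w = sum(self.tss_mixture.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError("TSS mixture weights must sum to 1")
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        if any(p >= self.primer_pos for p in self.tss_mixture):
            raise ValueError("all TSS positions must lie upstream of the primer")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        lo, hi = self.tail_len_range
        if not 1 <= lo <= hi:
            raise ValueError("bad tail length range")
        if self.read_len < len(self.anchor_seq) + hi + 20:
            raise ValueError("read_len too short to reach the locus insert")


def make_race_reads(
    locus: SyntheticLocus,
    spec: ReadSpec,
    out_fastq: str | Path | None = None,
) -> tuple[list[RaceRead], TruthRecord]:
    """Reads of the form anchor + poly-T + sense insert from TSS to primer.

    The insert is the sense-strand locus segment from the drawn TSS through
    the gene-specific primer position (the read is the reverse complement
    of the poly-dA-tailed cDNA), truncated to ``read_len``; substitution
    noise is applied uniformly across the read.
    """
    seq = locus.locus_seq
    if spec.anchor_seq in seq:
        raise ValueError("anchor sequence occurs in the locus")
    orf_start = locus.orf_start
    primer_end = orf_start + spec.primer_pos  # exclusive, includes c.primer_pos
    rng = np.random.default_rng(spec.seed)
    positions = sorted(spec.tss_mixture)
    weights = np.array([spec.tss_mixture[p] for p in positions])
    draws = rng.choice(len(positions), size=spec.n_reads, p=weights / weights.sum())
    tails = rng.integers(spec.tail_len_range[0], spec.tail_len_range[1] + 1,
                         size=spec.n_reads)
    reads: list[RaceRead] = []
    per_read_tss: dict[str, int] = {}
    for i in range(spec.n_reads):
        tss = positions[draws[i]]
        insert = seq[orf_start + tss : primer_end]
        full = spec.anchor_seq + "T" * int(tails[i]) + insert
        full = full[: spec.read_len]
        if spec.substitution_rate > 0:
            arr = np.frombuffer(full.encode(), dtype=np.uint8).copy()
            hit = rng.random(len(arr)) < spec.substitution_rate
            if hit.any():
                repl = rng.integers(0, 4, size=int(hit.sum()))
                lut = np.frombuffer(b"ACGT", dtype=np.uint8)
                new = lut[repl]
                same = new == arr[hit]
                # shift colliding draws to a different base
                new[same] = lut[(repl[same] + 1) % 4]
                arr[hit] = new
                full = arr.tobytes().decode()
        rid = f"read{i:06d}"
        reads.append(RaceRead(rid, full, "I" * len(full)))
        per_read_tss[rid] = tss
    counts = {p: int((draws == j).sum()) for j, p in enumerate(positions)}
    truth = TruthRecord(
        generator="make_race_reads",
        spec={**_spec_dict(spec),
              "tss_mixture": {str(k): v for k, v in spec.tss_mixture.items()}},
        truth={"per_read_tss": per_read_tss,
               "tss_counts": {str(k): v for k, v in counts.items()},
               "orf_start": orf_start},
    )
    if out_fastq is not None:
        with open(out_fastq, "w", encoding="utf-8") as fh:
            for r in reads:
                fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")
        truth.to_json(Path(out_fastq).with_suffix(".truth.json"))
    return reads, truth


# --- qPCR Ct tables ----------------------------------------------------------

@dataclass
class QpcrSpec:
    """Ct tables with known fold changes relative to a calibrator sample."""

    seed: int
    samples: tuple[str, ...] = ("control", "treated")
    calibrator: str = "control"
    target_genes: tuple[str, ...] = ("BTN1",)
    reference_gene: str = "ACT1"
    folds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"treated": {"BTN1": 2.0}}
    )
    target_baseline_ct: float = 24.0
    reference_baseline_ct: float = 18.0
    replicate_sd: float = 0.2
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.calibrator not in self.samples:
            raise ValueError("calibrator must be one of the samples")
        if self.replicate_sd < 0 or self.n_replicates < 1:
            raise ValueError("bad replicate settings")
        for sample, gene_folds in self.folds.items():
            if sample not in self.samples:
                raise ValueError(f"unknown sample {sample!r} in folds")
            for gene, fold in gene_folds.items():
                if gene not in self.target_genes:
                    raise ValueError(f"unknown gene {gene!r} in folds")
                if fold <= 0:
                    raise ValueError("fold changes must be positive")

    def fold(self, sample: str, gene: str) -> float:
        if sample == self.calibrator:
            return 1.0
        return self.folds.get(sample, {}).get(gene, 1.0)


def make_qpcr(
    spec: QpcrSpec, out_tsv: str | Path | None = None
) -> tuple[CtTable, TruthRecord]:
    """Ct = gene baseline - log2(fold) + Gaussian replicate noise."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for sample in spec.samples:
        for gene in (*spec.target_genes, spec.reference_gene):
            if gene == spec.reference_gene:
                base = spec.reference_baseline_ct
            else:
                base = spec.target_baseline_ct - np.log2(spec.fold(sample, gene))
            for rep in range(1, spec.n_replicates + 1):
                ct = base + rng.normal(0.0, spec.replicate_sd)
                rows.append((sample, gene, rep, round(float(ct), 6)))
    frame = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
    truth = TruthRecord(
        generator="make_qpcr",
        spec=_spec_dict(spec),
        truth={"folds": {s: dict(g) for s, g in spec.folds.items()},
               "calibrator": spec.calibrator},
    )
    if out_tsv is not None:
        frame.to_csv(out_tsv, sep="\t", index=False, float_format="%.6f")
        truth.to_json(Path(out_tsv).with_suffix(".truth.json"))
    return CtTable(frame), truth
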