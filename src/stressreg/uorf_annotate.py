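"""Annotation of upstream open reading frames (uORFs) in a gene's 5' leader.

Coordinates follow the HGVS-like ``c.`` convention: c.1 is the A of the main
start codon, c.-1 the base immediately upstream, and there is no position
zero.  A uORF "at -N" has the A of its ATG at c.-N; it is in frame with the
main ORF iff N is divisible by 3.

The module annotates every upstream ATG in a configurable window, lists the
stop codons lying in each uORF's frame before the main start codon, applies
in-silico start-codon knockouts (ATG -> AAG, reported as c.-(N-1)T>A edits),
and computes the probability of observing a run of stop codons under a
simple independent-codon null model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "STOP_CODONS",
    "LocusModel",
    "UorfAnnotation",
    "CodonModel",
    "scan_uorfs",
    "find_inframe_stops",
    "apply_start_knockouts",
    "stop_run_probability",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

_BASES = "ACGT"


def _validate_nt(seq: str, what: str) -> None:
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")


@dataclass(frozen=True)
class LocusModel:
    """A sense-strand 5' leader plus (optionally) the main ORF.

    ``upstream_seq`` runs 5'->3'; its last base is c.-1.  ``window`` bounds
    the uORF search: only ATGs whose A lies in [-window, -3] are reported.
    """

    upstream_seq: str
    main_orf_seq: str | None = None
    window: int = 192

    def __post_init__(self) -> None:
        _validate_nt(self.upstream_seq, "upstream_seq")
        if self.main_orf_seq is not None:
            _validate_nt(self.main_orf_seq, "main_orf_seq")
            if not self.main_orf_seq.startswith("ATG"):
                raise ValueError("main_orf_seq must begin with ATG (c.1 = A)")
        if self.window < 3:
            raise ValueError("window must be at least 3 bp")
        if self.window > len(self.upstream_seq):
            raise ValueError(
                f"window ({self.window}) exceeds upstream length "
                f"({len(self.upstream_seq)})"
            )

    def base_at(self, pos: int) -> str:
        """Base at a negative c. coordinate (c.-1 = last upstream base)."""
        if pos >= 0:
            raise ValueError("upstream coordinates are negative (no c.0)")
        idx = len(self.upstream_seq) + pos
        if idx < 0:
            raise ValueError(f"position {pos} outside the upstream sequence")
        return self.upstream_seq[idx]

    def codon_at(self, pos: int) -> str:
        """Codon whose first base is at negative c. coordinate ``pos``.

        Requires pos <= -3 so the codon fits entirely upstream of c.1.
        """
        if pos > -3:
            raise ValueError("codon must end at or before c.-1 (pos <= -3)")
        idx = len(self.upstream_seq) + pos
        if idx < 0:
            raise ValueError(f"position {pos} outside the upstream sequence")
        return self.upstream_seq[idx : idx + 3]


@dataclass(frozen=True)
class UorfAnnotation:
    """One upstream ATG: its position, frame class and in-frame stops."""

    start_pos: int
    frame: str  # "in_frame" | "out_of_frame" relative to the main ORF
    stops: tuple[tuple[int, str], ...]

    @property
    def terminated_before_main(self) -> bool:
        return len(self.stops) > 0

    def __post_init__(self) -> None:
        if self.start_pos > -3:
            raise ValueError("uORF start must be at c.-3 or more distal")
        expected = "in_frame" if self.start_pos % 3 == 0 else "out_of_frame"
        if self.frame != expected:
            raise ValueError(
                f"frame {self.frame!r} inconsistent with start {self.start_pos}"
            )


def scan_uorfs(locus: LocusModel) -> list[UorfAnnotation]:
    """All upstream ATGs with the A in [-window, -3], most distal first."""
    out: list[UorfAnnotation] = []
    for n in range(locus.window, 2, -1):
        if locus.codon_at(-n) == "ATG":
            out.append(_annotate(locus, -n))
    return out


def _annotate(locus: LocusModel, start_pos: int) -> UorfAnnotation:
    frame = "in_frame" if start_pos % 3 == 0 else "out_of_frame"
    stops = tuple(find_inframe_stops(locus, start_pos))
    return UorfAnnotation(start_pos=start_pos, frame=frame, stops=stops)


def find_inframe_stops(locus: LocusModel, start_pos: int) -> list[tuple[int, str]]:
    """Stop codons in the frame of ``start_pos``, 5'->3', before the main ATG.

    Positions are the c. coordinate of the codon's first base and lie
    strictly between ``start_pos`` and c.-1.  The search stops at c.-1;
    read-through into the main ORF is not followed.
    """
    if locus.codon_at(start_pos) != "ATG":
        raise ValueError(f"no ATG at c.{start_pos}")
    stops = []
    for p in range(start_pos + 3, -2, 3):
        if p > -3:
            break
        codon = locus.codon_at(p)
        if codon in STOP_CODONS:
            stops.append((p, codon))
    return stops


def apply_start_knockouts(
    locus: LocusModel, positions: list[int]
) -> tuple[LocusModel, list[str]]:
    """Convert ATG -> AAG at each uORF start; report HGVS-like c. edits.

    For a uORF at -N the T sits at c.-(N-1), so each edit reads
    ``c.-(N-1)T>A``.
    """
    seq = list(locus.upstream_seq)
    edits: list[str] = []
    for pos in positions:
        if locus.codon_at(pos) != "ATG":
            raise ValueError(f"no ATG at c.{pos}; cannot knock out")
        t_pos = pos + 1  # the T of ATG, one base 3' of the A
        seq[len(seq) + t_pos] = "A"
        edits.append(f"c.{t_pos}T>A")
    return replace(locus, upstream_seq="".join(seq)), edits


@dataclass(frozen=True)
class CodonModel:
    """Probability distribution over the 64 codons (independent draws)."""

    probs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.probs) != 64:
            raise ValueError("codon model must cover all 64 codons")
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("codon probabilities must be non-negative")
        if not math.isclose(sum(self.probs.values()), 1.0, rel_tol=1e-9):
            raise ValueError("codon probabilities must sum to 1")

    @classmethod
    def uniform(cls) -> "CodonModel":
        codons = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
        return cls({c: 1.0 / 64 for c in codons})

    @classmethod
    def composition(
        cls, p_a: float, p_c: float, p_g: float, p_t: float
    ) -> "CodonModel":
        """Codon probabilities as products of base frequencies."""
        base_p = {"A": p_a, "C": p_c, "G": p_g, "T": p_t}
        if not math.isclose(sum(base_p.values()), 1.0, rel_tol=1e-9):
            raise ValueError("base frequencies must sum to 1")
        probs = {
            "".join(c): base_p[c[0]] * base_p[c[1]] * base_p[c[2]]
            for c in itertools.product(_BASES, repeat=3)
        }
        return cls(probs)

    @property
    def p_stop(self) -> float:
        return sum(self.probs[c] for c in STOP_CODONS)


def stop_run_probability(
    n_codons: int, min_stops: int, model: CodonModel
) -> float:
    """P(at least ``min_stops`` stop codons among ``n_codons`` iid codons).

    Exact binomial tail summation with p_stop = model mass on TAA/TAG/TGA.
    """
    if not 0 <= min_stops <= n_codons:
        raise ValueError("require 0 <= min_stops <= n_codons")
    p = model.p_stop
    return sum(
        math.comb(n_codons, k) * p**k * (1 - p) ** (n_codons - k)
        for k in range(min_stops, n_codons + 1)
    )
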