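"""In-silico bisulfite pyrosequencing assay design.

Models the design procedure for methylation assays: bisulfite conversion of
the target region, exhaustive search for a CpG-free, SNP-free primer pair
near a target melting temperature flanking a 3-9 CpG window, and the
universal-tag second-round amplification scheme in which the reverse primer
carries a common biotinylated tail.

Primers are designed against the fully converted top strand (unmethylated
conversion); because their footprints are CpG-free, their converted sequence
is identical for methylated and unmethylated templates, which is what makes
the assay methylation-insensitive at the amplification step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "UNIVERSAL_TAG",
    "DesignConstraints",
    "AssayDesign",
    "NoDesignError",
    "bisulfite_convert",
    "primer_melting_temperature",
    "reverse_complement",
    "design_assay",
    "tag_second_round_primer",
]

# Universal second-round reverse-primer tail (biotinylated at 5'; the biotin
# is wet-lab metadata and not represented in the sequence).
UNIVERSAL_TAG = "CGCCAGGGTTTTCCCAGTCACGAC"

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class NoDesignError(ValueError):
    """Raised when no primer pair satisfies the design constraints."""


@dataclass(frozen=True)
class DesignConstraints:
    """Primer-design constraints.

    target_tm : target melting temperature in degC (Wallace rule).
    tm_tolerance : allowed deviation from target_tm, degC.
    primer_length_range : inclusive (min, max) primer length in nt.
    max_cpg_in_primer : CpG dinucleotides tolerated in a primer footprint
        (0 keeps the assay methylation-insensitive).
    flank_search_window : how far (bp) beyond each end of the target span
        primer footprints may start.
    forbid_snp_overlap : reject primers whose genomic footprint overlaps an
        annotated SNP.
    max_amplicon_length : upper bound on the amplified product, bp.
    """

    target_tm: float = 56.0
    tm_tolerance: float = 2.0
    primer_length_range: tuple[int, int] = (18, 30)
    max_cpg_in_primer: int = 0
    flank_search_window: int = 150
    forbid_snp_overlap: bool = True
    max_amplicon_length: int = 350

    def __post_init__(self) -> None:
        if self.target_tm <= 0:
            raise ValueError("target_tm must be positive")
        lo, hi = self.primer_length_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid primer_length_range {self.primer_length_range}")


@dataclass(frozen=True)
class AssayDesign:
    forward_primer: str
    reverse_primer: str
    tagged_reverse_primer: str
    amplicon_span: tuple[int, int]  # half-open, region coordinates
    sequence_to_analyze: str
    target_cpg_offsets: tuple[int, ...]  # offsets within sequence_to_analyze


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    for i, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise ValueError(f"invalid character {sequence[i]!r} at position {i}")
    return seq


def bisulfite_convert(sequence: str, state: str) -> str:
    """Convert a top-strand sequence as bisulfite treatment would read it.

    Every cytosine outside a CpG context deaminates to uracil (read T). A
    CpG cytosine survives as C when ``state='methylated'`` and converts to
    T when ``state='unmethylated'``. Length and non-C bases are preserved.
    """
    if state not in ("methylated", "unmethylated"):
        raise ValueError(f"state must be 'methylated' or 'unmethylated', got {state!r}")
    seq = _check_sequence(sequence)
    out = []
    n = len(seq)
    for i, base in enumerate(seq):
        if base != "C":
            out.append(base)
        elif i + 1 < n and seq[i + 1] == "G":
            out.append("C" if state == "methylated" else "T")
        else:
            out.append("T")
    return "".join(out)


def primer_melting_temperature(primer: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degC."""
    seq = primer.upper()
    if len(seq) < 8:
        raise ValueError("primer shorter than 8 nt")
    for i, base in enumerate(seq):
        if base not in "ACGT":
            raise ValueError(f"ambiguity code {primer[i]!r} at position {i}")
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def reverse_complement(sequence: str) -> str:
    return _check_sequence(sequence).translate(_COMPLEMENT)[::-1]


def tag_second_round_primer(reverse_primer: str) -> str:
    """Prefix the universal biotinylated tail onto a reverse primer."""
    if not reverse_primer:
        raise ValueError("empty primer")
    if reverse_primer.upper().startswith(UNIVERSAL_TAG):
        raise ValueError("already tagged")
    return UNIVERSAL_TAG + reverse_primer.upper()


def _cpg_positions(seq: str) -> list[int]:
    return [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


def _footprint_ok(
    genomic: str,
    start: int,
    length: int,
    snps_local: set[int],
    constraints: DesignConstraints,
) -> bool:
    """Shared footprint checks on the genomic (pre-conversion) region."""
    window = genomic[start : start + length]
    n_cpg = sum(1 for i in range(len(window) - 1) if window[i : i + 2] == "CG")
    # a CpG straddling the footprint's right edge still makes the first-base C
    # methylation sensitive
    if start + length < len(genomic) and genomic[start + length - 1 : start + length + 1] == "CG":
        n_cpg += 1
    if n_cpg > constraints.max_cpg_in_primer:
        return False
    if constraints.forbid_snp_overlap and any(
        start <= p < start + length for p in snps_local
    ):
        return False
    if "N" in window:
        return False
    return True


def design_assay(
    region: str,
    region_offset: int,
    target_span: tuple[int, int],
    snps: list[int],
    constraints: DesignConstraints = DesignConstraints(),
) -> AssayDesign:
    """Search a genomic region for a valid pyrosequencing primer pair.

    Parameters
    ----------
    region : genomic (pre-conversion) top-strand sequence.
    region_offset : genomic coordinate (1-based) of region[0]; SNP positions
        are genomic and converted internally.
    target_span : half-open (start, end) in region coordinates containing
        the CpGs to be read; must hold 3-9 CpGs.
    snps : 1-based genomic positions of annotated SNPs.

    The search is exhaustive over primer start/length combinations within
    ``flank_search_window`` of the target span and deterministic: among all
    feasible pairs the shortest amplicon wins, ties broken leftmost.
    """
    genomic = _check_sequence(region)
    t_start, t_end = target_span
    if not (0 <= t_start < t_end <= len(genomic)):
        raise ValueError(f"target_span {target_span} outside region")
    snps_local = {p - region_offset for p in snps if region_offset <= p < region_offset + len(genomic)}

    target_cpgs = [p for p in _cpg_positions(genomic) if t_start <= p < t_end]
    if not 3 <= len(target_cpgs) <= 9:
        raise NoDesignError(
            f"target span holds {len(target_cpgs)} CpGs; 3-9 required"
        )

    converted = bisulfite_convert(genomic, "unmethylated")
    lo, hi = constraints.primer_length_range
    tm_lo = constraints.target_tm - constraints.tm_tolerance
    tm_hi = constraints.target_tm + constraints.tm_tolerance

    fwd_min = max(0, t_start - constraints.flank_search_window)

    def tm_of(seq: str) -> float | None:
        if len(seq) < 8:
            return None
        return primer_melting_temperature(seq)

    # enumerate candidate forward primers (end at or before the first target CpG)
    forwards: list[tuple[int, int]] = []  # (start, length)
    rejections: dict[str, int] = {"tm": 0, "cpg_or_snp": 0}
    for start in range(fwd_min, t_start):
        for length in range(lo, hi + 1):
            end = start + length
            if end > t_start:
                break
            if not _footprint_ok(genomic, start, length, snps_local, constraints):
                rejections["cpg_or_snp"] += 1
                continue
            tm = tm_of(converted[start:end])
            if tm is None or not tm_lo <= tm <= tm_hi:
                rejections["tm"] += 1
                continue
            forwards.append((start, length))

    rev_max = min(len(genomic), t_end + constraints.flank_search_window)
    reverses: list[tuple[int, int]] = []
    for end in range(t_end + lo, rev_max + 1):
        for length in range(lo, hi + 1):
            start = end - length
            if start < t_end:
                break
            if not _footprint_ok(genomic, start, length, snps_local, constraints):
                rejections["cpg_or_snp"] += 1
                continue
            tm = tm_of(reverse_complement(bisulfite_convert(genomic, "methylated")[start:end]))
            # reverse primer anneals to the converted sense strand; its
            # footprint is CpG-free so methylated/unmethylated agree there
            if tm is None or not tm_lo <= tm <= tm_hi:
                rejections["tm"] += 1
                continue
            reverses.append((start, length))

    if not forwards or not reverses:
        raise NoDesignError(
            "no design: no feasible "
            + ("forward" if not forwards else "reverse")
            + f" primer (rejected {rejections['tm']} by Tm, "
            f"{rejections['cpg_or_snp']} by CpG/SNP/N footprint)"
        )

    best: tuple[int, int, tuple[int, int], tuple[int, int]] | None = None
    for f_start, f_len in forwards:
        for r_start, r_len in reverses:
            amp_len = (r_start + r_len) - f_start
            if amp_len > constraints.max_amplicon_length:
                continue
            key = (amp_len, f_start)
            if best is None or key < (best[0], best[1]):
                best = (amp_len, f_start, (f_start, f_len), (r_start, r_len))
    if best is None:
        raise NoDesignError(
            "no design: every primer pair exceeds "
            f"max_amplicon_length={constraints.max_amplicon_length}"
        )

    _, _, (f_start, f_len), (r_start, r_len) = best
    fwd_seq = converted[f_start : f_start + f_len]
    rev_seq = reverse_complement(
        bisulfite_convert(genomic, "methylated")[r_start : r_start + r_len]
    )
    seq_start, seq_end = f_start + f_len, r_start
    sequence_to_analyze = converted[seq_start:seq_end]
    offsets = tuple(p - seq_start for p in target_cpgs)
    return AssayDesign(
        forward_primer=fwd_seq,
        reverse_primer=rev_seq,
        tagged_reverse_primer=tag_second_round_primer(rev_seq),
        amplicon_span=(f_start, r_start + r_len),
        sequence_to_analyze=sequence_to_analyze,
        target_cpg_offsets=offsets,
    )
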