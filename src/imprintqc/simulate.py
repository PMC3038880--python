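"""Synthetic bisulfite-pyrosequencing data with ground truth.

Every generator emits the long-format methylation table the analysis
consumes together with a :class:`SyntheticTruth` record of the parameters
used, so each analysis stage can be tested for parameter recovery without
any external data.

The emulated structure mirrors imprinted-DMR biology: germ-line DMRs sit
near 50% in every somatic tissue; in testis (sperm) maternal germ-line
marks are erased (near 0%) and paternal ones are complete (near 100%);
maternally methylated somatic DMRs are tissue-specific while paternal
somatic DMRs stay in the differential range everywhere; paternally
methylated DMRs carry larger intra-CpG variability than maternal ones.
Technical noise is truncated Gaussian on the percent scale, per-CpG offsets
are fixed per (assay, CpG) across samples (systematic dispensation bias),
and allelic dropout at low template input replaces a 50% reading with a
draw near one rail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import MethylationDataset
from .dmr import DmrWindow, MethylationCategory, classify_value

__all__ = [
    "AssaySpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "default_tissue_panel_config",
    "default_blood_cohort_config",
    "default_dropout_model",
    "generate_tissue_panel",
    "generate_blood_cohort",
    "generate_standards",
    "generate_design_region",
    "generate_treatment_panel",
]

SOMATIC_TISSUES = ("brain", "breast", "colon", "heart", "kidney", "liver", "placenta")
ALL_TISSUES = SOMATIC_TISSUES + ("testis",)

#: Default technical noise (percent); on the order of the ~1.6% replicate
#: bias seen in standards-based validation of this assay class.
DEFAULT_MEASUREMENT_SD = 2.0
#: Default intra-CpG SDs; paternal DMRs are the more heterogeneous class.
DEFAULT_MATERNAL_CPG_SD = 2.0
DEFAULT_PATERNAL_CPG_SD = 5.0


@dataclass(frozen=True)
class AssaySpec:
    """True parameters of one simulated assay."""

    name: str
    parental_mark: str  # maternal / paternal / none / unknown
    timing: str         # germline / somatic / none / unknown
    true_profile: Mapping[str, float]  # tissue -> true percent
    intra_cpg_sd: float = DEFAULT_MATERNAL_CPG_SD
    n_cpgs: int = 5
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if not 3 <= self.n_cpgs <= 9:
            raise ValueError(f"{self.name}: n_cpgs must be in [3, 9]")
        for tissue, value in self.true_profile.items():
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{self.name}/{tissue}: true percent {value} outside [0, 100]")
        if self.intra_cpg_sd < 0:
            raise ValueError(f"{self.name}: intra_cpg_sd must be >= 0")


@dataclass
class SyntheticConfig:
    n_individuals: int
    tissues: tuple[str, ...]
    assays: tuple[AssaySpec, ...]
    measurement_sd: float = DEFAULT_MEASUREMENT_SD
    between_individual_sd: float = 1.5
    spiked_outliers: tuple[tuple[int, str, float], ...] = ()  # (individual idx, assay, shift)
    treatment_effect: Mapping[str, float] = field(default_factory=dict)  # assay -> fraction lost
    dose_multipliers: Mapping[str, float] = field(default_factory=lambda: {"#1": 0.8, "#2": 1.0})
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.measurement_sd < 0 or self.between_individual_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        names = [a.name for a in self.assays]
        if len(names) != len(set(names)):
            raise ValueError("duplicate assay names in config")
        for _, assay, _ in self.spiked_outliers:
            if assay not in names:
                raise ValueError(f"spiked outlier references unknown assay {assay!r}")
        for assay, frac in self.treatment_effect.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"treatment fraction for {assay} outside [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every simulated dataset."""

    true_means: dict[tuple[str, str], float] = field(default_factory=dict)  # (assay, tissue)
    categories: dict[str, MethylationCategory] = field(default_factory=dict)
    cpg_offsets: dict[str, tuple[float, ...]] = field(default_factory=dict)
    outlier_events: list[tuple[str, str, float]] = field(default_factory=list)  # (sample, assay, shift)
    dropout_events: list[tuple[str, float]] = field(default_factory=list)  # (sample, mass)
    standard_expected: dict[str, float] = field(default_factory=dict)  # sample -> expected percent
    treatment_fractions: dict[str, float] = field(default_factory=dict)

    def categorize(self, window: DmrWindow, tissues: Sequence[str]) -> dict[tuple[str, str], MethylationCategory]:
        """True category of every (assay, tissue) mean under a window."""
        return {
            key: classify_value(v, window) for key, v in self.true_means.items()
            if key[1] in tissues
        }


def _germline_testis_value(parental_mark: str) -> float:
    # sperm erase maternal imprints and carry paternal ones on both alleles
    return 2.0 if parental_mark == "maternal" else 98.0


def default_tissue_panel_config(seed: int = 0, n_individuals: int = 3) -> SyntheticConfig:
    """Tissue panel emulating the adult-tissue survey: eight tissues, three
    pooled individuals, germ-line DMRs near 50% in somatic tissue with
    testis erasure/completion, tissue-specific maternal somatic DMRs and
    stable paternal somatic DMRs."""

    def flat(value: float, testis: float | None = None) -> dict[str, float]:
        profile = {t: value for t in SOMATIC_TISSUES}
        profile["testis"] = value if testis is None else testis
        return profile

    assays = (
        # maternal germ-line: ~50 everywhere, erased in testis
        AssaySpec("gMAT1", "maternal", "germline", flat(50.0, 2.0), DEFAULT_MATERNAL_CPG_SD, 6, "clusterA"),
        AssaySpec("gMAT2", "maternal", "germline", flat(47.0, 2.0), DEFAULT_MATERNAL_CPG_SD, 5, "clusterA"),
        AssaySpec("gMAT3", "maternal", "germline", flat(53.0, 2.0), DEFAULT_MATERNAL_CPG_SD, 7),
        AssaySpec("gMAT4", "maternal", "germline", flat(44.0, 2.0), DEFAULT_MATERNAL_CPG_SD, 5),
        # paternal germ-line: ~50 everywhere, fully methylated in sperm
        AssaySpec("gPAT1", "paternal", "germline", flat(50.0, 98.0), DEFAULT_PATERNAL_CPG_SD, 5, "clusterB"),
        AssaySpec("gPAT2", "paternal", "germline", flat(55.0, 98.0), DEFAULT_PATERNAL_CPG_SD, 4),
        # maternal somatic: differential in one or two tissues only
        AssaySpec(
            "sMAT1", "maternal", "somatic",
            {**{t: 22.0 for t in SOMATIC_TISSUES}, "brain": 50.0, "testis": 20.0},
            DEFAULT_MATERNAL_CPG_SD, 5, "clusterB",
        ),
        AssaySpec(
            "sMAT2", "maternal", "somatic",
            {**{t: 75.0 for t in SOMATIC_TISSUES}, "liver": 48.0, "testis": 72.0},
            DEFAULT_MATERNAL_CPG_SD, 6,
        ),
        # paternal somatic: differential everywhere
        AssaySpec("sPAT1", "paternal", "somatic", flat(45.0), DEFAULT_PATERNAL_CPG_SD, 5),
        AssaySpec("sPAT2", "paternal", "somatic", flat(57.0), DEFAULT_PATERNAL_CPG_SD, 6),
        # non-DMR controls: rails
        AssaySpec("ctrlHYPO", "none", "none", flat(8.0), 1.5, 4),
        AssaySpec("ctrlHYPER", "none", "none", flat(90.0), 1.5, 4),
    )
    return SyntheticConfig(
        n_individuals=n_individuals,
        tissues=ALL_TISSUES,
        assays=assays,
        seed=seed,
    )


def default_blood_cohort_config(
    seed: int = 0,
    n_individuals: int = 50,
    maternal_cpg_sd: float = DEFAULT_MATERNAL_CPG_SD,
    paternal_cpg_sd: float = DEFAULT_PATERNAL_CPG_SD,
    spiked_outliers: tuple[tuple[int, str, float], ...] = (),
) -> SyntheticConfig:
    """Blood cohort emulating the 50-individual inter-individual survey:
    a representative mix of maternal/paternal, germ-line/somatic DMRs with
    cluster structure, one value vector per individual."""
    blood = lambda v: {"blood": v}  # noqa: E731
    assays = []
    maternal_true = [50.0, 47.0, 52.0, 45.0, 49.0, 51.0, 48.0, 53.0, 46.0, 50.5, 44.0, 54.0]
    paternal_true = [50.0, 48.0, 55.0, 43.0, 52.0, 47.0, 51.0, 49.0, 45.5, 53.5, 46.5]
    clusters = {0: "cis1", 1: "cis1", 2: "cis2", 3: "cis2", 4: "cis2"}
    for i, v in enumerate(maternal_true):
        assays.append(AssaySpec(
            f"mDMR{i + 1}", "maternal", "germline" if i % 2 == 0 else "somatic",
            blood(v), maternal_cpg_sd, 5 + (i % 3), clusters.get(i),
        ))
    for i, v in enumerate(paternal_true):
        assays.append(AssaySpec(
            f"pDMR{i + 1}", "paternal", "germline" if i % 2 == 0 else "somatic",
            blood(v), paternal_cpg_sd, 4 + (i % 4), "cis3" if i < 2 else None,
        ))
    return SyntheticConfig(
        n_individuals=n_individuals,
        tissues=("blood",),
        assays=tuple(assays),
        spiked_outliers=spiked_outliers,
        seed=seed,
    )


def _clip(values: np.ndarray) -> np.ndarray:
    return np.clip(values, 0.0, 100.0)


def _draw_cpg_offsets(rng: np.random.Generator, config: SyntheticConfig) -> dict[str, np.ndarray]:
    return {
        a.name: rng.normal(0.0, a.intra_cpg_sd, size=a.n_cpgs)
        for a in config.assays
    }


def generate_tissue_panel(config: SyntheticConfig) -> tuple[MethylationDataset, SyntheticTruth]:
    """Per-CpG readings for every assay x tissue x individual.

    value = clip(true_profile[tissue] + cpg_offset + eps, 0, 100) with
    cpg_offset ~ N(0, intra_cpg_sd) fixed per (assay, CpG) and
    eps ~ N(0, measurement_sd) per reading. A germ-line assay whose profile
    omits 'testis' gets the erasure/completion value for its parental mark.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    offsets = _draw_cpg_offsets(rng, config)
    truth = SyntheticTruth(cpg_offsets={k: tuple(v) for k, v in offsets.items()})

    rows = []
    for assay in config.assays:
        for tissue in config.tissues:
            if tissue in assay.true_profile:
                true = assay.true_profile[tissue]
            elif tissue == "testis" and assay.timing == "germline":
                true = _germline_testis_value(assay.parental_mark)
            else:
                raise ValueError(f"{assay.name}: no true value for tissue {tissue!r}")
            truth.true_means[(assay.name, tissue)] = true
            for ind in range(1, config.n_individuals + 1):
                sample = f"{tissue}_ind{ind}"
                eps = rng.normal(0.0, config.measurement_sd, size=assay.n_cpgs) \
                    if config.measurement_sd > 0 else np.zeros(assay.n_cpgs)
                vals = _clip(true + offsets[assay.name] + eps)
                for cpg, v in enumerate(vals, start=1):
                    rows.append((assay.name, sample, cpg, v, tissue, f"ind{ind}",
                                 "tissue_panel"))
    df = pd.DataFrame(rows, columns=["assay", "sample", "cpg_index", "percent",
                                     "tissue", "individual", "group"])
    return MethylationDataset(df), truth


def generate_blood_cohort(config: SyntheticConfig) -> tuple[MethylationDataset, SyntheticTruth]:
    """Per-CpG readings for a blood cohort, one value set per individual.

    Each individual draws a true level N(assay blood mean,
    between_individual_sd); spiked outliers add their stated shift on top
    and are recorded in the truth. Per-CpG offsets are fixed per assay as
    in the tissue panel, so paternal assays (larger intra_cpg_sd) show the
    wider per-sample CpG scatter.
    """
    config.validate()
    if config.tissues != ("blood",):
        raise ValueError("blood cohort config must have tissues=('blood',)")
    rng = np.random.default_rng(config.seed)
    offsets = _draw_cpg_offsets(rng, config)
    truth = SyntheticTruth(cpg_offsets={k: tuple(v) for k, v in offsets.items()})
    spikes = {(f"ind{i}", a): shift for i, a, shift in config.spiked_outliers}

    rows = []
    for assay in config.assays:
        true = assay.true_profile["blood"]
        truth.true_means[(assay.name, "blood")] = true
        for ind in range(1, config.n_individuals + 1):
            ind_id = f"ind{ind}"
            sample = f"blood_{ind_id}"
            ind_true = true + rng.normal(0.0, config.between_individual_sd)
            shift = spikes.get((ind_id, assay.name), 0.0)
            if shift:
                truth.outlier_events.append((sample, assay.name, shift))
            eps = rng.normal(0.0, config.measurement_sd, size=assay.n_cpgs) \
                if config.measurement_sd > 0 else np.zeros(assay.n_cpgs)
            vals = _clip(ind_true + shift + offsets[assay.name] + eps)
            for cpg, v in enumerate(vals, start=1):
                rows.append((assay.name, sample, cpg, v, "blood", ind_id, "blood"))
    df = pd.DataFrame(rows, columns=["assay", "sample", "cpg_index", "percent",
                                     "tissue", "individual", "group"])
    return MethylationDataset(df), truth


def default_dropout_model(mass_ng: float) -> float:
    """Probability of allelic dropout per replicate at a template mass.

    Dropout is a low-template failure mode: rare at 1 ng, absent above."""
    return 0.05 if mass_ng <= 1.0 else 0.0


def generate_standards(
    noise_sd: float,
    reps: int = 2,
    masses_ng: Sequence[float] = (),
    seed: int = 0,
    dropout_model: Callable[[float], float] = default_dropout_model,
    n_cpgs: int = 5,
    assay: str = "STD",
) -> tuple[MethylationDataset, SyntheticTruth]:
    """Standard-mixture series plus optional input-titration 50% standards.

    Emits the 0/25/50/75/100% series (``reps`` replicates each, Gaussian
    noise, clipped) in group 'standard'; for each mass in ``masses_ng`` it
    emits 50% standards whose replicates drop out with probability
    ``dropout_model(mass)``, a dropout replacing the reading with a draw
    near 0 or 100 (equal odds), recorded in the truth.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if any(m <= 0 for m in masses_ng):
        raise ValueError("template masses must be positive")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    rows = []
    for expected in (0.0, 25.0, 50.0, 75.0, 100.0):
        for rep in range(1, reps + 1):
            sample = f"mix{int(expected)}_rep{rep}"
            truth.standard_expected[sample] = expected
            vals = _clip(expected + rng.normal(0.0, noise_sd, size=n_cpgs)) \
                if noise_sd > 0 else np.full(n_cpgs, expected)
            for cpg, v in enumerate(vals, start=1):
                rows.append((assay, sample, cpg, v, "standard", rep, np.nan, expected))
    for mass in masses_ng:
        p_drop = dropout_model(mass)
        if not 0.0 <= p_drop <= 1.0:
            raise ValueError(f"dropout probability {p_drop} outside [0, 1]")
        for rep in range(1, reps + 1):
            sample = f"mass{mass:g}_rep{rep}"
            truth.standard_expected[sample] = 50.0
            if rng.random() < p_drop:
                rail = 0.0 if rng.random() < 0.5 else 100.0
                vals = _clip(rail + rng.uniform(0.0, 3.0, size=n_cpgs) * (1 if rail == 0 else -1))
                truth.dropout_events.append((sample, float(mass)))
            else:
                vals = _clip(50.0 + rng.normal(0.0, noise_sd, size=n_cpgs)) \
                    if noise_sd > 0 else np.full(n_cpgs, 50.0)
            for cpg, v in enumerate(vals, start=1):
                rows.append((assay, sample, cpg, v, "standard", rep, float(mass), 50.0))
    df = pd.DataFrame(rows, columns=["assay", "sample", "cpg_index", "percent",
                                     "group", "replicate", "template_mass_ng",
                                     "expected_percent"])
    return MethylationDataset(df), truth


def _primer_site(rng: np.random.Generator, length: int = 20, n_g: int = 8) -> str:
    """A CpG- and C-free site whose bisulfite-converted sequence has a
    Wallace melting temperature of exactly 2*(length-n_g) + 4*n_g degC
    (56 degC for the defaults)."""
    bases = ["G"] * n_g + [("A" if rng.random() < 0.5 else "T") for _ in range(length - n_g)]
    rng.shuffle(bases)
    return "".join(bases)


def generate_design_region(
    island_length: int,
    island_cpg_count: int,
    snp_positions: Sequence[int] = (),
    seed: int = 0,
    flank_length: int = 120,
) -> tuple[str, list[int], dict]:
    """Random region with a CpG island of an exact CpG count and CpG-free
    flanks each admitting at least one 56 degC primer site.

    Returns (sequence, snp positions (1-based, region-local), truth dict
    with the island span, midpoint, primer-site spans and CpG count). The
    feasibility of both primer sites is verified by an exhaustive Wallace
    Tm check before returning.
    """
    if island_cpg_count < 0 or island_length < 2 * island_cpg_count:
        raise ValueError(
            f"{island_cpg_count} CpGs not realizable in {island_length} bp"
        )
    if flank_length < 40:
        raise ValueError("flank_length must be >= 40")
    rng = np.random.default_rng(seed)

    def at_filler(n: int) -> str:
        return "".join("A" if rng.random() < 0.5 else "T" for _ in range(n))

    site_len = 20
    left_site = _primer_site(rng, site_len)
    right_site = _primer_site(rng, site_len)
    pad = (flank_length - site_len) // 2
    left_flank = at_filler(pad) + left_site + at_filler(flank_length - site_len - pad)
    right_flank = at_filler(pad) + right_site + at_filler(flank_length - site_len - pad)

    # island: exactly island_cpg_count CG dinucleotides, A/T filler
    if island_cpg_count > 0:
        gap = island_length // island_cpg_count
        if gap < 2:
            raise ValueError("island too dense to realize")
        island_chars = []
        placed = 0
        i = 0
        while i < island_length:
            if placed < island_cpg_count and i % gap == 0 and i + 1 < island_length:
                island_chars.append("CG")
                placed += 1
                i += 2
            else:
                island_chars.append("A" if rng.random() < 0.5 else "T")
                i += 1
        island = "".join(island_chars)
        if placed < island_cpg_count:
            raise ValueError("could not place all CpGs; increase island_length")
    else:
        island = at_filler(island_length)

    sequence = left_flank + island + right_flank
    island_start = len(left_flank)
    island_end = island_start + len(island)

    # exhaustive feasibility check: a 56 degC, CpG-free 20-mer on each side
    from .design import bisulfite_convert, primer_melting_temperature, reverse_complement

    converted = bisulfite_convert(sequence, "unmethylated")

    def has_site(lo: int, hi: int, reverse: bool) -> bool:
        for start in range(lo, hi - site_len + 1):
            window = sequence[start : start + site_len + 1]
            if "CG" in window:
                continue
            primer = converted[start : start + site_len]
            if reverse:
                primer = reverse_complement(primer)
            if primer_melting_temperature(primer) == 56.0:
                return True
        return False

    if not has_site(0, island_start, reverse=False):
        raise RuntimeError("internal check failed: no forward primer site")
    if not has_site(island_end, len(sequence), reverse=True):
        raise RuntimeError("internal check failed: no reverse primer site")

    truth = {
        "island_span": (island_start, island_end),
        "midpoint": island_start + len(island) // 2,
        "cpg_count": island.count("CG"),
        "left_primer_site": (pad, pad + site_len),
        "right_primer_site": (island_end + pad, island_end + pad + site_len),
    }
    return sequence, [int(p) for p in snp_positions], truth


def generate_treatment_panel(
    config: SyntheticConfig,
) -> tuple[dict[str, float], dict[str, dict[str, float]], SyntheticTruth]:
    """Control and per-dose treated assay means for a demethylation run.

    The control mean is each assay's first-tissue true value; dose '#d'
    loses fraction ``dose_multipliers[d] * treatment_effect[assay]`` of the
    control methylation, plus measurement noise. Fractions are recorded in
    the truth for recovery testing.
    """
    config.validate()
    if not config.treatment_effect:
        raise ValueError("config.treatment_effect is empty")
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth(treatment_fractions=dict(config.treatment_effect))
    tissue0 = config.tissues[0]
    control: dict[str, float] = {}
    treated: dict[str, dict[str, float]] = {d: {} for d in config.dose_multipliers}
    for assay in config.assays:
        if assay.name not in config.treatment_effect:
            continue
        true = assay.true_profile[tissue0]
        control[assay.name] = float(_clip(np.array([true + rng.normal(0, config.measurement_sd)]))[0])
        frac = config.treatment_effect[assay.name]
        for dose, mult in config.dose_multipliers.items():
            lost = min(1.0, frac * mult)
            treated[dose][assay.name] = float(
                _clip(np.array([true * (1.0 - lost) + rng.normal(0, config.measurement_sd)]))[0]
            )
    return control, treated, truth
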