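"""Forward simulation of a multiparent advanced-intercross haploid collection.

The simulator emulates the construction of a mitonuclear recombinant
collection: a panel of divergent haploid founders drawn from structured
ancestral populations is intercrossed through repeated rounds of random
MATa × MATα mating and meiosis, a sample of F_n haploids is taken, and each
sampled nuclear genome is replicated across several mitotypes (isonuclear
replication). Petite colony counts are then sampled binomially from a
planted phenotype architecture with nuclear main effects, mitotype effects,
SNP×mitotype interactions and covariate effects on the logit scale.

Crossovers follow a Haldane (no-interference) model: between adjacent
markers at map distance d cM, the allele origin switches with probability
r = (1 - exp(-2 d / 100)) / 2; chromosomes segregate independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .pheno import GrowthCurve

__all__ = [
    "GeneticMap",
    "Chromosome",
    "FounderPanel",
    "RecombinantCollection",
    "PhenotypeArchitecture",
    "AssayDesign",
    "haldane_r",
    "stage_rng",
    "simulate_founders",
    "meiosis",
    "advanced_intercross",
    "replicate_with_mitotypes",
    "simulate_petite_counts",
    "plant_architecture",
    "simulate_growth_curve",
    "simulate_ct_records",
    "simulate_mtgenome",
]

MISSING = -1

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
]


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage random stream derived from a master seed.

    The child stream is seeded by ``SeedSequence([master_seed, crc32(stage)])``
    — a fixed, documented derivation, so any stage can be re-run in
    isolation and still reproduce exactly.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def haldane_r(d_cm) -> np.ndarray:
    """Haldane recombination fraction for a map distance in cM.

    Strictly increasing in d, r(0) = 0 and r -> 0.5 as d -> infinity.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


@dataclass
class Chromosome:
    name: str
    length_bp: int
    pos_bp: np.ndarray
    pos_cm: np.ndarray

    def __post_init__(self) -> None:
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: length must be > 0")
        if self.pos_bp.shape != self.pos_cm.shape or self.pos_bp.ndim != 1:
            raise ValueError(f"{self.name}: bp and cM position arrays must match")
        if np.any(np.diff(self.pos_bp) <= 0):
            raise ValueError(f"{self.name}: bp positions must be strictly increasing")
        if np.any(np.diff(self.pos_cm) < 0):
            raise ValueError(f"{self.name}: cM positions must be nondecreasing")
        if self.pos_bp.size and (self.pos_bp[0] < 1 or self.pos_bp[-1] > self.length_bp):
            raise ValueError(f"{self.name}: marker positions outside chromosome")

    @property
    def n_markers(self) -> int:
        return self.pos_bp.size


@dataclass
class GeneticMap:
    """Marker map over one or more chromosomes (bp and cM coordinates)."""

    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self.chromosomes)

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length_bp for c in self.chromosomes}

    def marker_frame(self) -> pd.DataFrame:
        """Long table of markers: chrom, pos (bp), cm."""
        parts = [
            pd.DataFrame({"chrom": c.name, "pos": c.pos_bp, "cm": c.pos_cm})
            for c in self.chromosomes
        ]
        return pd.concat(parts, ignore_index=True)

    def marker_chrom_index(self) -> np.ndarray:
        return np.repeat(
            np.arange(len(self.chromosomes)), [c.n_markers for c in self.chromosomes]
        )

    def switch_probabilities(self) -> np.ndarray:
        """Per-marker probability that gamete allele origin switches
        relative to the previous marker; 0.5 at every chromosome start
        (independent segregation)."""
        probs = np.empty(self.n_markers, dtype=float)
        off = 0
        for c in self.chromosomes:
            m = c.n_markers
            if m == 0:
                continue
            probs[off] = 0.5
            if m > 1:
                probs[off + 1 : off + m] = haldane_r(np.diff(c.pos_cm))
            off += m
        return probs

    def default_mat_marker(self) -> int:
        """Marker index used as the mating-type locus: middle marker of the
        third chromosome (or of the last one when fewer exist)."""
        ci = min(2, len(self.chromosomes) - 1)
        off = sum(c.n_markers for c in self.chromosomes[:ci])
        return off + self.chromosomes[ci].n_markers // 2

    @classmethod
    def yeast_like(
        cls,
        n_chromosomes: int = 16,
        markers_per_chromosome: int = 1560,
        chromosome_length_bp: int = 750_000,
        cm_per_kb: float = 0.4,
    ) -> "GeneticMap":
        """An evenly spaced yeast-like map (default ~25k markers over 16
        chromosomes, ~0.4 cM/kb)."""
        chroms = []
        for i in range(n_chromosomes):
            pos = np.round(
                chromosome_length_bp
                * (np.arange(1, markers_per_chromosome + 1))
                / (markers_per_chromosome + 1)
            ).astype(np.int64)
            pos = np.unique(pos)
            chroms.append(
                Chromosome(
                    name=f"chr{_ROMAN[i]}" if i < len(_ROMAN) else f"chr{i + 1}",
                    length_bp=chromosome_length_bp,
                    pos_bp=pos,
                    pos_cm=pos / 1000.0 * cm_per_kb,
                )
            )
        return cls(chroms)


@dataclass
class FounderPanel:
    """Haploid founder panel drawn from structured ancestral populations."""

    founder_ids: list[str]
    population: np.ndarray
    mating_type: np.ndarray
    haplotypes: np.ndarray  # (n_founders, n_markers) int8 in {0,1}
    gmap: GeneticMap
    pop_freqs: np.ndarray  # (n_populations, n_markers)
    ancestral_freq: np.ndarray
    F: float

    def __post_init__(self) -> None:
        n = len(self.founder_ids)
        if self.haplotypes.shape != (n, self.gmap.n_markers):
            raise ValueError("haplotype matrix shape does not match panel")
        if n < 2:
            raise ValueError("need >= 2 founders for intercrossing")

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)


def simulate_founders(
    n_founders: int = 25,
    n_populations: int = 5,
    gmap: GeneticMap | None = None,
    F: float = 0.2,
    seed=None,
) -> FounderPanel:
    """Simulate a structured founder panel.

    Per-marker ancestral allele frequencies are drawn uniformly on
    (0.1, 0.9); each ancestral population receives its own frequency from a
    Beta(p(1-F)/F, (1-p)(1-F)/F) distribution (Balding–Nichols two-level
    sampling) so that Var(p_pop) = F p(1-p). Founders are assigned to
    populations as evenly as possible and their haplotypes are Bernoulli
    draws from the population frequencies. Mating types alternate so every
    population carries both.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders for intercrossing")
    if not 1 <= n_populations <= n_founders:
        raise ValueError("n_populations must be in [1, n_founders]")
    if not 0.0 <= F < 1.0:
        raise ValueError(f"F must be in [0, 1), got {F}")
    if gmap is None:
        gmap = GeneticMap.yeast_like()
    rng = _as_rng(seed)
    m = gmap.n_markers
    p_anc = rng.uniform(0.1, 0.9, size=m)
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        pop_freqs = rng.beta(a, b, size=(n_populations, m))
    else:
        pop_freqs = np.tile(p_anc, (n_populations, 1))
    pop_of = np.arange(n_founders) % n_populations
    haps = (rng.random((n_founders, m)) < pop_freqs[pop_of]).astype(np.int8)
    return FounderPanel(
        founder_ids=[f"F{i + 1:02d}" for i in range(n_founders)],
        population=np.array([f"P{p + 1}" for p in pop_of]),
        mating_type=np.array(["MATa" if i % 2 == 0 else "MATalpha" for i in range(n_founders)]),
        haplotypes=haps,
        gmap=gmap,
        pop_freqs=pop_freqs,
        ancestral_freq=p_anc,
        F=F,
    )


def _gametes(
    haps_a: np.ndarray,
    haps_b: np.ndarray,
    switch_probs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised meiosis for a batch of diploids (rows pair haps_a/haps_b).

    Returns gametes and the boolean origin track (True where the allele came
    from the b-parent).
    """
    n, m = haps_a.shape
    u = rng.random((n, m), dtype=np.float32)
    switch = u < switch_probs.astype(np.float32)
    from_b = np.logical_xor.accumulate(switch, axis=1)
    return np.where(from_b, haps_b, haps_a), from_b


def meiosis(parent_hap_a, parent_hap_b, gmap: GeneticMap, seed=None) -> np.ndarray:
    """One meiotic product of the diploid formed by two haploid parents.

    The gamete allele origin follows a Markov chain along each chromosome
    with Haldane switch probability r(d) between adjacent markers;
    chromosomes segregate independently.
    """
    a = np.asarray(parent_hap_a, dtype=np.int8)
    b = np.asarray(parent_hap_b, dtype=np.int8)
    if a.shape != b.shape or a.ndim != 1 or a.size != gmap.n_markers:
        raise ValueError("parent haplotypes must be 1-D and match the marker set")
    rng = _as_rng(seed)
    gam, _ = _gametes(a[None, :], b[None, :], gmap.switch_probabilities(), rng)
    return gam[0]


@dataclass
class RecombinantCollection:
    """Strains × markers haploid genotype matrix with per-row metadata.

    ``strains`` has one row per strain × mitotype replicate (columns:
    ``strain_id``, ``mitotype``, ``mating_type``, plus any covariate
    columns); ``genotypes`` rows align with it. Nuclear genotypes are
    identical across rows sharing a strain_id (isonuclear replication).
    Genotype entries are 0/1 with -1 for missing.
    """

    strains: pd.DataFrame
    genotypes: np.ndarray
    gmap: GeneticMap
    ancestry: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.strains), self.gmap.n_markers):
            raise ValueError("genotype matrix shape does not match strain table / map")
        vals = np.unique(self.genotypes)
        if not np.all(np.isin(vals, [MISSING, 0, 1])):
            raise ValueError("genotype entries must be in {0, 1, -1}")

    @property
    def n_rows(self) -> int:
        return len(self.strains)

    @property
    def mitotypes(self) -> list[str]:
        return sorted(self.strains["mitotype"].unique())

    def unique_nuclear(self) -> tuple[pd.DataFrame, np.ndarray]:
        """One row per strain (first occurrence): metadata and genotypes."""
        first = ~self.strains["strain_id"].duplicated()
        return self.strains.loc[first].reset_index(drop=True), self.genotypes[first.to_numpy()]


def advanced_intercross(
    panel: FounderPanel,
    rounds: int = 7,
    progeny_per_round: int = 10_000,
    sample_size: int = 181,
    seed=None,
    mat_marker: int | None = None,
    mitotype_label: str = "RC1",
    aux_markers: list[int] | None = None,
    chunk_size: int = 2048,
) -> RecombinantCollection:
    """Advanced intercross: repeated rounds of random MATa × MATα mating.

    Each round pairs random MATa × MATα individuals, sporulates the
    resulting diploids (one meiosis per progeny) and keeps
    ``progeny_per_round`` haploids. Progeny mating type segregates with the
    mating-type locus (a designated marker, by default mid-chromosome 3):
    a gamete is MATa exactly when it inherited that region from its MATa
    parent. After the final round, ``sample_size`` haploids are drawn
    without replacement. ``rounds=0`` samples founder haplotypes directly.

    Founder-ancestry tracks are propagated per marker, so genome-wide
    ancestry fractions and LD decay can be audited. Optional ``aux_markers``
    expose the genotype at chosen markers as auxotrophy covariate columns
    (``aux1`` ...).
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    rng = _as_rng(seed)
    gmap = panel.gmap
    m = gmap.n_markers
    if mat_marker is None:
        mat_marker = gmap.default_mat_marker()
    if not 0 <= mat_marker < m:
        raise ValueError("mat_marker outside marker set")

    haps = panel.haplotypes.astype(np.int8)
    anc = np.tile(np.arange(panel.n_founders, dtype=np.int32)[:, None], (1, m))
    is_a = panel.mating_type == "MATa"

    if rounds == 0:
        take = rng.choice(
            panel.n_founders, size=sample_size, replace=sample_size > panel.n_founders
        )
        haps, anc, is_a = haps[take], anc[take], is_a[take]
    else:
        if sample_size > progeny_per_round:
            raise ValueError("sample_size must be <= progeny_per_round")
        switch_probs = gmap.switch_probabilities()
        for _ in range(rounds):
            a_idx = np.nonzero(is_a)[0]
            b_idx = np.nonzero(~is_a)[0]
            if a_idx.size == 0 or b_idx.size == 0:
                raise ValueError("no compatible MATa x MATalpha mating pairs")
            new_h = np.empty((progeny_per_round, m), dtype=np.int8)
            new_a = np.empty((progeny_per_round, m), dtype=np.int32)
            new_mt = np.empty(progeny_per_round, dtype=bool)
            for lo in range(0, progeny_per_round, chunk_size):
                hi = min(lo + chunk_size, progeny_per_round)
                pa = rng.choice(a_idx, size=hi - lo)
                pb = rng.choice(b_idx, size=hi - lo)
                gam, from_b = _gametes(haps[pa], haps[pb], switch_probs, rng)
                new_h[lo:hi] = gam
                new_a[lo:hi] = np.where(from_b, anc[pb], anc[pa])
                # MATa parent is pa; gamete is MATa iff MAT locus came from pa
                new_mt[lo:hi] = ~from_b[:, mat_marker]
            haps, anc, is_a = new_h, new_a, new_mt
        take = rng.choice(progeny_per_round, size=sample_size, replace=False)
        haps, anc, is_a = haps[take], anc[take], is_a[take]

    strains = pd.DataFrame(
        {
            "strain_id": [f"S{i + 1:04d}" for i in range(sample_size)],
            "mitotype": mitotype_label,
            "mating_type": np.where(is_a, "MATa", "MATalpha"),
        }
    )
    for k, idx in enumerate(aux_markers or []):
        strains[f"aux{k + 1}"] = haps[:, idx].astype(int)
    return RecombinantCollection(strains=strains, genotypes=haps, gmap=gmap, ancestry=anc)


def replicate_with_mitotypes(
    rc: RecombinantCollection, mitotype_labels: list[str]
) -> RecombinantCollection:
    """Replicate every strain across mitotypes (isonuclear replication).

    The input must have exactly one row per strain; the output has one row
    per strain × label with identical nuclear genotypes and covariates
    within a strain.
    """
    if len(mitotype_labels) != len(set(mitotype_labels)):
        raise ValueError(f"mitotype labels must be distinct: {mitotype_labels}")
    if rc.strains["strain_id"].duplicated().any():
        dup = rc.strains.loc[rc.strains["strain_id"].duplicated(), "strain_id"].iloc[0]
        raise ValueError(f"duplicate strain_id in input collection: {dup}")
    frames, geno, anc = [], [], []
    for label in mitotype_labels:
        df = rc.strains.copy()
        df["mitotype"] = label
        frames.append(df)
        geno.append(rc.genotypes)
        if rc.ancestry is not None:
            anc.append(rc.ancestry)
    return RecombinantCollection(
        strains=pd.concat(frames, ignore_index=True),
        genotypes=np.vstack(geno),
        gmap=rc.gmap,
        ancestry=np.vstack(anc) if anc else None,
    )


@dataclass
class PhenotypeArchitecture:
    """Planted effects on the logit (log-odds) petite-probability scale.

    ``baseline`` is the logit of the petite probability for a reference row;
    ``main_effects`` maps marker index -> beta; ``mito_effects`` maps
    mitotype label -> beta; ``interaction_effects`` maps
    (marker index, mitotype) -> delta (effect added only in that mitotype);
    ``covariate_effects`` maps a numeric covariate column -> gamma.
    ``overdispersion`` >= 1 is the variance-inflation factor of the colony
    counts relative to binomial sampling.
    """

    baseline: float
    main_effects: dict[int, float] = field(default_factory=dict)
    mito_effects: dict[str, float] = field(default_factory=dict)
    interaction_effects: dict[tuple[int, str], float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    overdispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")

    def snp_indices(self) -> set[int]:
        return set(self.main_effects) | {i for i, _ in self.interaction_effects}


@dataclass
class AssayDesign:
    """Petite-assay sampling design: colonies plated per assay and
    replicate assays per strain row."""

    colonies_per_assay: int = 500
    replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.colonies_per_assay < 1:
            raise ValueError("colonies_per_assay must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def simulate_petite_counts(
    rc: RecombinantCollection,
    arch: PhenotypeArchitecture,
    design: AssayDesign,
    seed=None,
) -> pd.DataFrame:
    """Sample petite colony counts under a planted architecture.

    For each strain row and replicate, ``petite_count ~ Binomial(n, p)``
    with ``p = expit(linear predictor)``; when ``overdispersion > 1`` the
    probability is first jittered by a beta-mixing step calibrated so the
    count variance is inflated by exactly that factor
    (``1 + (n-1)/(s+1) = overdispersion``).
    """
    m = rc.gmap.n_markers
    bad = [i for i in arch.snp_indices() if not 0 <= i < m]
    if bad:
        raise ValueError(f"architecture references markers outside the map: {bad}")
    for cov in arch.covariate_effects:
        if cov not in rc.strains.columns:
            raise ValueError(f"architecture references unknown covariate {cov!r}")
    rng = _as_rng(seed if seed is not None else design.seed)

    eta = np.full(rc.n_rows, arch.baseline, dtype=float)
    for idx, beta in arch.main_effects.items():
        g = rc.genotypes[:, idx].astype(float)
        g[rc.genotypes[:, idx] == MISSING] = np.nan
        eta += beta * np.nan_to_num(g)
    mito = rc.strains["mitotype"].to_numpy()
    for label, beta in arch.mito_effects.items():
        eta += beta * (mito == label)
    for (idx, label), delta in arch.interaction_effects.items():
        g = (rc.genotypes[:, idx] == 1).astype(float)
        eta += delta * g * (mito == label)
    for cov, gamma in arch.covariate_effects.items():
        eta += gamma * rc.strains[cov].to_numpy(dtype=float)
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)

    n = design.colonies_per_assay
    records = []
    for rep in range(1, design.replicates + 1):
        if arch.overdispersion > 1.0:
            if n == 1:
                raise ValueError("overdispersion undefined for single-colony assays")
            s = (n - 1) / (arch.overdispersion - 1.0) - 1.0
            if s <= 0:
                raise ValueError(
                    f"overdispersion {arch.overdispersion} not attainable with {n} colonies"
                )
            p_rep = rng.beta(p * s, (1 - p) * s)
        else:
            p_rep = p
        counts = rng.binomial(n, p_rep)
        records.append(
            pd.DataFrame(
                {
                    "strain_id": rc.strains["strain_id"],
                    "mitotype": rc.strains["mitotype"],
                    "replicate": rep,
                    "petite_count": counts,
                    "total_count": n,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def plant_architecture(
    rc: RecombinantCollection,
    baseline_pct: float = 5.0,
    beta_main: float = 1.0,
    n_interaction: int = 3,
    delta: float = 1.5,
    interaction_mitotype: str | None = None,
    target_maf: float = 0.3,
    maf_window: float = 0.07,
    mito_effects: dict[str, float] | None = None,
    min_separation_bp: int = 100_000,
    edge_buffer_bp: int = 25_000,
    seed=None,
) -> tuple[PhenotypeArchitecture, pd.DataFrame]:
    """Choose planted loci at a target MAF and build an architecture.

    One main-effect locus (``beta_main`` logit units) and ``n_interaction``
    interaction loci (``delta`` logit units, expressed only in
    ``interaction_mitotype``, default the last sorted label) are picked
    among markers whose observed MAF is within ``maf_window`` of
    ``target_maf``, preferring distinct chromosomes and enforcing
    ``min_separation_bp``. Markers within ``edge_buffer_bp`` of a
    chromosome end are excluded so planted loci survive telomere masking.
    Returns the architecture and a table of the chosen loci (marker index,
    chrom, pos, maf, role).
    """
    rng = _as_rng(seed)
    _, geno = rc.unique_nuclear()
    freq = np.nanmean(np.where(geno == MISSING, np.nan, geno).astype(float), axis=0)
    maf = np.minimum(freq, 1 - freq)
    markers = rc.gmap.marker_frame()
    lengths = markers["chrom"].map(rc.gmap.chrom_lengths).to_numpy()
    pos_all = markers["pos"].to_numpy()
    interior = (pos_all > edge_buffer_bp) & (pos_all <= lengths - edge_buffer_bp)
    candidates = np.nonzero((np.abs(maf - target_maf) <= maf_window) & interior)[0]
    if candidates.size < n_interaction + 1:
        raise ValueError(
            f"only {candidates.size} markers near MAF {target_maf}; need {n_interaction + 1}"
        )
    candidates = rng.permutation(candidates)
    chosen: list[int] = []
    for idx in candidates:
        ok = all(
            markers.loc[idx, "chrom"] != markers.loc[j, "chrom"]
            or abs(int(markers.loc[idx, "pos"]) - int(markers.loc[j, "pos"]))
            >= min_separation_bp
            for j in chosen
        )
        if ok:
            chosen.append(int(idx))
        if len(chosen) == n_interaction + 1:
            break
    if len(chosen) < n_interaction + 1:
        raise ValueError("could not place loci with the requested separation")
    labels = rc.mitotypes
    target_label = interaction_mitotype if interaction_mitotype is not None else labels[-1]
    if target_label not in labels:
        raise ValueError(f"unknown mitotype {target_label!r}")
    main_locus, inter_loci = chosen[0], chosen[1:]
    arch = PhenotypeArchitecture(
        baseline=float(logit(baseline_pct / 100.0)),
        main_effects={main_locus: beta_main},
        mito_effects=dict(mito_effects or {}),
        interaction_effects={(i, target_label): delta for i in inter_loci},
    )
    info = pd.DataFrame(
        {
            "marker": chosen,
            "chrom": [markers.loc[i, "chrom"] for i in chosen],
            "pos": [int(markers.loc[i, "pos"]) for i in chosen],
            "maf": [float(maf[i]) for i in chosen],
            "role": ["main"] + ["interaction"] * n_interaction,
        }
    )
    return arch, info


def simulate_growth_curve(
    K: float = 1.0,
    r: float = 0.4,
    t0: float = 8.0,
    schedule=None,
    noise_sd: float = 0.0,
    seed=None,
) -> GrowthCurve:
    """Logistic OD600 curve ``K / (1 + exp(-r (t - t0)))`` plus Gaussian noise.

    Default schedule: 15-minute sampling over 24 h. ``r`` is in 1/h; the
    analytic maximal slope of the noiseless curve is r·K/4 OD/h.
    """
    if K <= 0:
        raise ValueError("carrying capacity K must be > 0")
    if r < 0:
        raise ValueError("growth rate r must be >= 0")
    t = np.arange(0.0, 24.0 + 1e-9, 0.25) if schedule is None else np.asarray(schedule, float)
    if t.size == 0:
        raise ValueError("schedule must be nonempty")
    od = K / (1.0 + np.exp(-r * (t - t0)))
    if noise_sd > 0:
        od = od + _as_rng(seed).normal(0.0, noise_sd, size=t.size)
    return GrowthCurve(time_h=t, od=od)


def simulate_ct_records(
    true_expression,
    control_expression,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    seed=None,
    ct_intercept: float = 40.0,
) -> pd.DataFrame:
    """qPCR cycle-threshold table under ``Ct = a - log_eff(template)``.

    With perfect efficiency (2), doubling the template lowers Ct by exactly
    one cycle. Returns a table with columns ``sample``, ``ct_candidate``,
    ``ct_control``.
    """
    cand = np.asarray(true_expression, dtype=float)
    ctrl = np.asarray(control_expression, dtype=float)
    if cand.shape != ctrl.shape or cand.ndim != 1:
        raise ValueError("expression vectors must be 1-D and equal length")
    if np.any(cand <= 0) or np.any(ctrl <= 0):
        raise ValueError("expression levels must be > 0")
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must be in (1, 2]")
    rng = _as_rng(seed)
    log_eff = np.log(efficiency)
    ct_cand = ct_intercept - np.log(cand) / log_eff
    ct_ctrl = ct_intercept - np.log(ctrl) / log_eff
    if noise_sd > 0:
        ct_cand = ct_cand + rng.normal(0, noise_sd, cand.size)
        ct_ctrl = ct_ctrl + rng.normal(0, noise_sd, ctrl.size)
    return pd.DataFrame(
        {
            "sample": [f"sample{i + 1}" for i in range(cand.size)],
            "ct_candidate": ct_cand,
            "ct_control": ct_ctrl,
        }
    )


def simulate_mtgenome(
    backbone_length: int = 80_000,
    backbone_gc: float = 5.0,
    class_counts: dict[str, int] | None = None,
    motif_library=None,
    seed=None,
    return_placements: bool = False,
):
    """AT-rich mtDNA-like backbone with GC-cluster motifs planted in it.

    ``class_counts`` requests instances per cluster class; motifs are placed
    at random non-overlapping positions (>= 1 bp apart) by overwriting the
    backbone, preserving total length. ``backbone_gc`` is the percent GC of
    the backbone alone.
    """
    if backbone_length < 1:
        raise ValueError("backbone_length must be >= 1")
    class_counts = dict(class_counts or {})
    rng = _as_rng(seed)
    placements: list[tuple[int, str, str]] = []
    if any(c > 0 for c in class_counts.values()):
        if motif_library is None or len(motif_library) == 0:
            raise ValueError("nonzero cluster counts requested but motif library is empty")
        missing = [c for c in class_counts if c not in motif_library.motifs]
        if missing:
            raise ValueError(f"no motifs for requested classes: {missing}")
        instances: list[tuple[str, str]] = []
        for label in sorted(class_counts):
            seqs = motif_library.motifs[label]
            for k in range(class_counts[label]):
                instances.append((label, seqs[k % len(seqs)]))
        order = rng.permutation(len(instances))
        instances = [instances[i] for i in order]
        total = sum(len(s) for _, s in instances)
        n_inst = len(instances)
        free = backbone_length - total - (n_inst - 1)
        if free < 0:
            raise ValueError(
                f"motifs ({total} bp + spacing) do not fit in backbone of {backbone_length} bp"
            )
        offsets = np.sort(rng.choice(free + 1, size=n_inst, replace=free + 1 >= n_inst))
        cursor = 0
        for k, (label, motif) in enumerate(instances):
            start = int(offsets[k]) + cursor + k  # k enforces >=1 bp gaps
            placements.append((start, label, motif))
            cursor += len(motif)
    gc = backbone_gc / 100.0
    probs = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    seq = rng.choice(np.array(list("GCAT")), size=backbone_length, p=probs)
    for start, _, motif in placements:
        seq[start : start + len(motif)] = list(motif)
    sequence = "".join(seq)
    if return_placements:
        df = pd.DataFrame(
            [
                {"cls": label, "start": start + 1, "end": start + len(motif)}
                for start, label, motif in sorted(placements)
            ],
            columns=["cls", "start", "end"],
        )
        return sequence, df
    return sequence
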