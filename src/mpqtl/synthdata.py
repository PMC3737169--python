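"""Synthetic multiparent mapping populations.

Emulates the data structure of an 8-founder recombinant-inbred-line (RIL)
resource mapped by crossing two populations (pA, pB), each founded by seven
unique inbred lines plus one line (AB8) shared between the populations.  The
generator produces, in order:

1. founder SNP haplotypes (and optional rare TE insertions),
2. RIL genomes as mosaics of founder segments (Poisson breakpoints on the
   cM scale, a small residual-heterozygosity fraction),
3. a soft emulation of the HMM output real resources ship: per-RIL
   probabilities over the 36 founder-genotype states (8 homozygous + 28
   unordered heterozygous) on a regular bp grid, collapsed to 8 additive
   founder probabilities,
4. pA-male x pB-female F1 cross designs between compatible subpopulations
   (pA1 x pB2 and pA2 x pB1),
5. replicated count phenotypes (fecundity after drug exposure) driven by
   planted QTL effects, a subpopulation shift, weekly block effects, a
   cross-level polygenic term and replicate noise.

Everything is deterministic under a seed; a single global seed fans out to
per-component child seeds so each stage is independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap

__all__ = [
    "FOUNDERS_A",
    "FOUNDERS_B",
    "N_FOUNDERS",
    "STATE_PAIRS",
    "FounderPanel",
    "MosaicGenome",
    "GenotypeProbTensor",
    "HaplotypeProbSet",
    "QTLEffectSpec",
    "SimulatedPhenotypes",
    "simulate_founder_panel",
    "simulate_founder_pair",
    "simulate_ril_mosaic",
    "simulate_ril_set",
    "emulate_hmm",
    "collapse_to_additive",
    "make_crosses",
    "simulate_phenotypes",
    "qtl_genetic_values",
    "calibrate_qtl_effects",
    "child_seed",
]

N_FOUNDERS = 8
FOUNDERS_A = ["A1", "A2", "A3", "A4", "A5", "A6", "A7", "AB8"]
FOUNDERS_B = ["B1", "B2", "B3", "B4", "B5", "B6", "B7", "AB8"]

#: the 36 unordered founder-genotype states: 8 homozygous then 28 heterozygous
STATE_PAIRS: list[tuple[int, int]] = [
    (i, j) for i in range(N_FOUNDERS) for j in range(i, N_FOUNDERS)
]
_STATE_INDEX = {pair: k for k, pair in enumerate(STATE_PAIRS)}

# 36x8 collapse matrix: heterozygous states contribute 1/2 to each founder
_ADDITIVE = np.zeros((len(STATE_PAIRS), N_FOUNDERS))
for _k, (_i, _j) in enumerate(STATE_PAIRS):
    if _i == _j:
        _ADDITIVE[_k, _i] = 1.0
    else:
        _ADDITIVE[_k, _i] = 0.5
        _ADDITIVE[_k, _j] = 0.5


def child_seed(seed: int, *tags) -> int:
    """Deterministic child seed (< 2**31) derived from a parent seed and tags.

    Tags are hashed with a stable digest (not Python's salted ``hash``) so
    the fan-out is reproducible across processes.
    """
    import hashlib

    digests = [
        int.from_bytes(hashlib.blake2s(repr(t).encode()).digest()[:4], "little") % (2**31)
        for t in tags
    ]
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *digests])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# founder panels
# ---------------------------------------------------------------------------


@dataclass
class FounderPanel:
    """Eight inbred founder haplotypes for one population.

    ``snps`` has columns (arm, pos_bp) plus one 0/1 allele column per founder
    (1 = minor allele across the panel pair).  ``tes`` is an optional table of
    rare transposable-element insertions with the same founder columns coding
    presence/absence.
    """

    population: str  # "pA" | "pB"
    founders: list[str]
    snps: pd.DataFrame
    tes: pd.DataFrame | None = None

    def alleles_at(self, row: int) -> np.ndarray:
        return self.snps.iloc[row][self.founders].to_numpy(dtype=float)


def _validate_maf_spec(maf_spec: dict) -> tuple[float, float]:
    if maf_spec.get("dist", "uniform") != "uniform":
        raise ValueError(f"unsupported maf_spec distribution: {maf_spec}")
    lo, hi = float(maf_spec["low"]), float(maf_spec["high"])
    if not (0.0 < lo < hi <= 0.5):
        raise ValueError("maf_spec must have support inside (0, 0.5]")
    return lo, hi


def _draw_snp_table(
    n_snps: int, gmap: GeneticMap, maf_spec: dict, founders: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    lo, hi = _validate_maf_spec(maf_spec)
    arms = gmap.arm_names
    lengths = np.array([gmap.arm_length_bp(a) for a in arms], dtype=float)
    cols = {"arm": [], "pos_bp": []}
    if n_snps:
        arm_idx = rng.choice(len(arms), size=n_snps, p=lengths / lengths.sum())
        pos = np.floor(rng.uniform(0, lengths[arm_idx])).astype(int)
        cols["arm"] = [arms[i] for i in arm_idx]
        cols["pos_bp"] = pos
    df = pd.DataFrame(cols)
    # target MAF drawn from the spec; number of minor-allele founders is the
    # nearest achievable count out of 8, at least 1 (SNPs are segregating)
    maf = rng.uniform(lo, hi, size=n_snps)
    carriers = np.clip(np.rint(maf * N_FOUNDERS).astype(int), 1, N_FOUNDERS // 2)
    alleles = np.zeros((n_snps, N_FOUNDERS), dtype=np.int8)
    for s in range(n_snps):
        alleles[s, rng.choice(N_FOUNDERS, size=carriers[s], replace=False)] = 1
    for f, name in enumerate(founders):
        df[name] = alleles[:, f] if n_snps else np.array([], dtype=np.int8)
    df = df.sort_values(["arm", "pos_bp"], kind="stable").reset_index(drop=True)
    return df


def _draw_te_table(
    te_spec: dict, gmap: GeneticMap, founders: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    n_te = int(te_spec.get("n_te", 0))
    max_carriers = int(te_spec.get("max_carriers", 2))
    arms = gmap.arm_names
    lengths = np.array([gmap.arm_length_bp(a) for a in arms], dtype=float)
    rows = []
    for t in range(n_te):
        ai = rng.choice(len(arms), p=lengths / lengths.sum())
        pos = int(rng.uniform(0, lengths[ai]))
        k = int(rng.integers(1, max_carriers + 1))
        carriers = rng.choice(N_FOUNDERS, size=k, replace=False)
        alleles = np.zeros(N_FOUNDERS, dtype=np.int8)
        alleles[carriers] = 1
        rows.append({"te_id": f"TE{t + 1}", "arm": arms[ai], "pos_bp": pos,
                     **dict(zip(founders, alleles))})
    return pd.DataFrame(rows, columns=["te_id", "arm", "pos_bp", *founders])


def simulate_founder_panel(
    n_snps: int,
    gmap: GeneticMap,
    maf_spec: dict,
    te_spec: dict | None = None,
    seed: int = 0,
    population: str = "pA",
) -> FounderPanel:
    """Simulate one population's founder panel.

    SNP positions are uniform over the arms; per SNP the minor-allele founder
    count is the value nearest 8 x MAF for a MAF drawn from ``maf_spec``
    (uniform over (low, high]).
    """
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    founders = FOUNDERS_A if population == "pA" else FOUNDERS_B
    rng = np.random.default_rng(seed)
    snps = _draw_snp_table(n_snps, gmap, maf_spec, founders, rng)
    tes = _draw_te_table(te_spec, gmap, founders, rng) if te_spec else None
    return FounderPanel(population=population, founders=founders, snps=snps, tes=tes)


def simulate_founder_pair(
    n_snps: int,
    gmap: GeneticMap,
    maf_spec: dict,
    te_spec: dict | None = None,
    seed: int = 0,
) -> tuple[FounderPanel, FounderPanel]:
    """Simulate pA and pB panels sharing SNP positions and the AB8 haplotype.

    The same physical SNPs segregate in both panels (as they would after joint
    variant calling across all 15 founders) and the shared founder AB8 carries
    identical alleles in both.
    """
    pa = simulate_founder_panel(n_snps, gmap, maf_spec, te_spec, seed=child_seed(seed, "pA"),
                                population="pA")
    rng = np.random.default_rng(child_seed(seed, "pB-alleles"))
    lo, hi = _validate_maf_spec(maf_spec)
    snps_b = pa.snps[["arm", "pos_bp"]].copy()
    n = len(snps_b)
    maf = rng.uniform(lo, hi, size=n)
    carriers = np.clip(np.rint(maf * N_FOUNDERS).astype(int), 1, N_FOUNDERS // 2)
    alleles = np.zeros((n, N_FOUNDERS), dtype=np.int8)
    ab8 = pa.snps["AB8"].to_numpy()
    for s in range(n):
        # AB8's allele is fixed by the pA panel; fill remaining carriers among B1-B7
        need = carriers[s] - ab8[s]
        alleles[s, 7] = ab8[s]
        if need > 0:
            alleles[s, rng.choice(7, size=min(int(need), 7), replace=False)] = 1
    for f, name in enumerate(FOUNDERS_B):
        snps_b[name] = alleles[:, f] if n else np.array([], dtype=np.int8)
    tes_b = None
    if pa.tes is not None:
        rng_te = np.random.default_rng(child_seed(seed, "pB-te"))
        tes_b = pa.tes[["te_id", "arm", "pos_bp"]].copy()
        al = np.zeros((len(tes_b), N_FOUNDERS), dtype=np.int8)
        ab8_te = pa.tes["AB8"].to_numpy()
        for t in range(len(tes_b)):
            al[t, 7] = ab8_te[t]
            if not ab8_te[t] and rng_te.random() < 0.5:
                al[t, rng_te.integers(0, 7)] = 1
        for f, name in enumerate(FOUNDERS_B):
            tes_b[name] = al[:, f]
    pb = FounderPanel(population="pB", founders=FOUNDERS_B, snps=snps_b, tes=tes_b)
    return pa, pb


# ---------------------------------------------------------------------------
# RIL mosaics
# ---------------------------------------------------------------------------


@dataclass
class MosaicGenome:
    """One RIL genome as founder segments per arm.

    ``segments[arm]`` is a list of ``(start_bp, end_bp, (f1, f2))`` with
    half-open [start, end) intervals tiling [0, arm_length); f1 <= f2 are
    founder indices, equal for the (typical) homozygous case.
    """

    ril_id: str
    subpop: str  # pA1|pA2|pB1|pB2
    segments: dict[str, list[tuple[int, int, tuple[int, int]]]]

    def state_at(self, arm: str, bp: int) -> tuple[int, int]:
        for start, end, state in self.segments[arm]:
            if start <= bp < end:
                return state
        raise KeyError(f"{bp} outside arm {arm} of {self.ril_id}")


def simulate_ril_mosaic(
    panel: FounderPanel,
    gmap: GeneticMap,
    breakpoint_rate: float,
    het_fraction: float = 0.0,
    seed: int = 0,
    ril_id: str = "RIL1",
    subpop: str = "pA1",
) -> MosaicGenome:
    """Simulate one RIL genome.

    Breakpoints are a Poisson process on the cM scale with intensity
    ``breakpoint_rate`` per Morgan; founder identity per segment is uniform
    over the 8 founders (so a fraction 1/8 of nominal breakpoints join equal
    founders and are merged away).  A fraction ``het_fraction`` of segments
    (hence, in expectation, of the genome) is left residually heterozygous
    with a second uniformly drawn founder.
    """
    if breakpoint_rate < 0:
        raise ValueError("breakpoint_rate must be >= 0")
    if not (0 <= het_fraction < 1):
        raise ValueError("het_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    segments: dict[str, list[tuple[int, int, tuple[int, int]]]] = {}
    for arm in gmap.arm_names:
        length_bp = gmap.arm_length_bp(arm)
        length_m = gmap.arm_length_cm(arm) / 100.0
        n_bp = rng.poisson(breakpoint_rate * length_m)
        cms = np.sort(rng.uniform(0, gmap.arm_length_cm(arm), size=n_bp))
        bps = np.unique(np.floor(gmap.cm_to_bp(arm, cms)).astype(int))
        bps = bps[(bps > 0) & (bps < length_bp)]
        bounds = np.concatenate([[0], bps, [length_bp]])
        founders = rng.integers(0, N_FOUNDERS, size=len(bounds) - 1)
        segs: list[tuple[int, int, tuple[int, int]]] = []
        for k in range(len(founders)):
            f = int(founders[k])
            state = (f, f)
            if het_fraction and rng.random() < het_fraction:
                other = int(rng.integers(0, N_FOUNDERS - 1))
                other += other >= f
                state = (min(f, other), max(f, other))
            start, end = int(bounds[k]), int(bounds[k + 1])
            if segs and segs[-1][2] == state:
                segs[-1] = (segs[-1][0], end, state)  # merge equal neighbours
            else:
                segs.append((start, end, state))
        segments[arm] = segs
    return MosaicGenome(ril_id=ril_id, subpop=subpop, segments=segments)


def simulate_ril_set(
    panel: FounderPanel,
    gmap: GeneticMap,
    n_rils: int,
    breakpoint_rate: float,
    het_fraction: float = 0.0,
    seed: int = 0,
    subpops: tuple[str, str] | None = None,
) -> list[MosaicGenome]:
    """Simulate ``n_rils`` RILs split evenly over a population's two subpopulations."""
    if subpops is None:
        subpops = ("pA1", "pA2") if panel.population == "pA" else ("pB1", "pB2")
    prefix = panel.population
    out = []
    for i in range(n_rils):
        sp = subpops[0] if i < (n_rils + 1) // 2 else subpops[1]
        out.append(
            simulate_ril_mosaic(
                panel, gmap, breakpoint_rate, het_fraction,
                seed=child_seed(seed, "ril", i), ril_id=f"{prefix}_{i + 1}", subpop=sp,
            )
        )
    return out


# ---------------------------------------------------------------------------
# HMM emulation and additive collapse
# ---------------------------------------------------------------------------


@dataclass
class GenotypeProbTensor:
    """Per-RIL probabilities over the 36 founder-genotype states on a bp grid."""

    ril_id: str
    grid: pd.DataFrame  # columns arm, pos_bp
    probs: np.ndarray  # (n_positions, 36)


def emulate_hmm(
    mosaic: MosaicGenome,
    certainty: float,
    grid_bp: int = 10_000,
    seed: int = 0,
    soft_fraction: float = 0.05,
) -> GenotypeProbTensor:
    """Emulate HMM founder-state assignment on a regular grid.

    At a ``1 - soft_fraction`` share of grid points the true state receives
    probability >= ``certainty`` (the rest spread over two random alternative
    states); at the remaining "soft" points the true state receives a reduced
    share, mimicking uncertainty near recombination breakpoints.  With
    ``certainty=1`` the output is exactly the one-hot truth.
    """
    if not (0 < certainty <= 1):
        raise ValueError("certainty must be in (0, 1]")
    if grid_bp <= 0:
        raise ValueError("grid_bp must be positive")
    rng = np.random.default_rng(seed)
    grid_rows = []
    true_states = []
    for arm, segs in mosaic.segments.items():
        length = segs[-1][1]
        pos = np.arange(0, length, grid_bp, dtype=int)
        grid_rows.append(pd.DataFrame({"arm": arm, "pos_bp": pos}))
        bounds = np.array([s[0] for s in segs] + [segs[-1][1]])
        idx = np.searchsorted(bounds, pos, side="right") - 1
        true_states.extend(_STATE_INDEX[segs[k][2]] for k in idx)
    grid = pd.concat(grid_rows, ignore_index=True)
    n = len(grid)
    true_states = np.asarray(true_states)
    probs = np.zeros((n, len(STATE_PAIRS)))
    if certainty == 1.0:
        probs[np.arange(n), true_states] = 1.0
        return GenotypeProbTensor(mosaic.ril_id, grid, probs)
    soft = rng.random(n) < soft_fraction
    p_true = np.where(
        soft, rng.uniform(0.35, certainty, size=n), rng.uniform(certainty, 1.0, size=n)
    )
    n_states = len(STATE_PAIRS)
    rows = np.arange(n)
    # two distinct alternative states per row, never equal to the true state
    o1 = rng.integers(0, n_states - 1, size=n)
    o1 += o1 >= true_states
    o2 = rng.integers(0, n_states - 2, size=n)
    lo = np.minimum(true_states, o1)
    hi = np.maximum(true_states, o1)
    o2 += o2 >= lo
    o2 += o2 >= hi
    split = rng.random(n)  # uniform split of the leftover mass
    probs[rows, true_states] = p_true
    probs[rows, o1] = (1.0 - p_true) * split
    probs[rows, o2] = (1.0 - p_true) * (1.0 - split)
    probs /= probs.sum(axis=1, keepdims=True)
    return GenotypeProbTensor(mosaic.ril_id, grid, probs)


def collapse_to_additive(probs36: GenotypeProbTensor) -> np.ndarray:
    """Collapse 36 genotype-state probabilities to 8 additive founder probabilities.

    Heterozygous states are treated as intermediate between the two homozygous
    states: founder i receives P(i,i) + 1/2 sum_j P(i,j).  Row sums are
    preserved at 1.
    """
    return probs36.probs @ _ADDITIVE


@dataclass
class HaplotypeProbSet:
    """Additive founder probabilities for a set of RILs on a common grid.

    ``probs`` has shape (n_rils, n_positions, 8); ``grid`` carries
    (arm, pos_bp, pos_cM) and is ordered by arm then position.
    """

    population: str
    ril_ids: list[str]
    subpops: dict[str, str]
    grid: pd.DataFrame
    probs: np.ndarray
    founders: list[str] = field(default_factory=lambda: list(FOUNDERS_A))

    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {r: i for i, r in enumerate(self.ril_ids)}

    def index_of(self, ril_ids) -> np.ndarray:
        try:
            return np.array([self._index[r] for r in ril_ids])
        except KeyError as exc:  # pragma: no cover - error path
            raise KeyError(f"no probability rows for RIL {exc.args[0]!r}") from exc

    def position_index(self, arm: str, pos_bp: int) -> int:
        """Index of the grid point nearest (arm, pos_bp)."""
        mask = self.grid["arm"].to_numpy() == arm
        if not mask.any():
            raise KeyError(f"arm {arm!r} not on grid")
        pos = self.grid["pos_bp"].to_numpy()[mask]
        local = int(np.argmin(np.abs(pos - pos_bp)))
        return int(np.flatnonzero(mask)[local])

    @classmethod
    def from_mosaics(
        cls,
        mosaics: list[MosaicGenome],
        gmap: GeneticMap,
        certainty: float = 0.95,
        grid_bp: int = 10_000,
        seed: int = 0,
        soft_fraction: float = 0.05,
    ) -> "HaplotypeProbSet":
        tensors = [
            emulate_hmm(m, certainty, grid_bp, seed=child_seed(seed, "hmm", m.ril_id),
                        soft_fraction=soft_fraction)
            for m in mosaics
        ]
        grid = tensors[0].grid.copy()
        probs = np.stack([collapse_to_additive(t) for t in tensors])
        grid["pos_cM"] = [
            float(gmap.bp_to_cm(a, p)) for a, p in zip(grid["arm"], grid["pos_bp"])
        ]
        population = "pA" if mosaics[0].subpop.startswith("pA") else "pB"
        founders = FOUNDERS_A if population == "pA" else FOUNDERS_B
        return cls(
            population=population,
            ril_ids=[m.ril_id for m in mosaics],
            subpops={m.ril_id: m.subpop for m in mosaics},
            grid=grid,
            probs=probs,
            founders=list(founders),
        )


# ---------------------------------------------------------------------------
# crosses and phenotypes
# ---------------------------------------------------------------------------

_COMPATIBLE = {("pA1", "pB2"): "A1B2", ("pA2", "pB1"): "A2B1"}


def make_crosses(
    pa_rils: list[MosaicGenome],
    pb_rils: list[MosaicGenome],
    pairing: str | list[tuple[str, str]] = "index",
) -> pd.DataFrame:
    """Pair pA males with pB females into an F1 cross design.

    Only the matched subpopulation combinations pA1 x pB2 and pA2 x pB1 are
    admissible; any other pairing raises.  ``pairing="index"`` pairs the i-th
    compatible pA RIL with the i-th compatible pB RIL (emulating crossing
    lines with the same line number); an explicit list of
    (pa_ril_id, pb_ril_id) pairs is also accepted.
    """
    by_id_a = {m.ril_id: m for m in pa_rils}
    by_id_b = {m.ril_id: m for m in pb_rils}
    pairs: list[tuple[MosaicGenome, MosaicGenome]]
    if pairing == "index":
        a1 = [m for m in pa_rils if m.subpop == "pA1"]
        a2 = [m for m in pa_rils if m.subpop == "pA2"]
        b1 = [m for m in pb_rils if m.subpop == "pB1"]
        b2 = [m for m in pb_rils if m.subpop == "pB2"]
        pairs = list(zip(a1, b2)) + list(zip(a2, b1))
    else:
        pairs = [(by_id_a[a], by_id_b[b]) for a, b in pairing]
    rows = []
    for k, (pa, pb) in enumerate(pairs):
        combo = _COMPATIBLE.get((pa.subpop, pb.subpop))
        if combo is None:
            raise ValueError(
                f"incompatible cross {pa.ril_id}({pa.subpop}) x {pb.ril_id}({pb.subpop}); "
                "only pA1 x pB2 and pA2 x pB1 are crossed"
            )
        rows.append(
            {"cross_id": f"X{k + 1:04d}", "paternal": pa.ril_id, "maternal": pb.ril_id,
             "subpop_combo": combo}
        )
    return pd.DataFrame(rows, columns=["cross_id", "paternal", "maternal", "subpop_combo"])


@dataclass
class QTLEffectSpec:
    """Generative truth for one QTL: founder effect vectors in phenotype units.

    Effect vectors are centred to mean zero on construction (the location is
    absorbed by the grand mean); ``target_fraction`` optionally records the
    intended share of total genetic variance for calibration.
    """

    arm: str
    pos_bp: int
    paternal_effects: np.ndarray
    maternal_effects: np.ndarray
    target_fraction: float | None = None

    def __post_init__(self):
        self.paternal_effects = np.asarray(self.paternal_effects, dtype=float)
        self.maternal_effects = np.asarray(self.maternal_effects, dtype=float)
        if self.paternal_effects.shape != (N_FOUNDERS,) or self.maternal_effects.shape != (
            N_FOUNDERS,
        ):
            raise ValueError("effect vectors must have length 8")
        self.paternal_effects = self.paternal_effects - self.paternal_effects.mean()
        self.maternal_effects = self.maternal_effects - self.maternal_effects.mean()


def qtl_genetic_values(
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    qtl: QTLEffectSpec,
) -> np.ndarray:
    """Per-cross genetic value contributed by one QTL."""
    ia = probsA.position_index(qtl.arm, qtl.pos_bp)
    ib = probsB.position_index(qtl.arm, qtl.pos_bp)
    if abs(int(probsA.grid["pos_bp"].iloc[ia]) - qtl.pos_bp) >= 10_000:
        raise ValueError(f"QTL position {qtl.arm}:{qtl.pos_bp} is off the probability grid")
    ga = probsA.probs[probsA.index_of(design["paternal"]), ia, :]
    gb = probsB.probs[probsB.index_of(design["maternal"]), ib, :]
    return ga @ qtl.paternal_effects + gb @ qtl.maternal_effects


def calibrate_qtl_effects(
    qtls: list[QTLEffectSpec],
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    var_genetic_total: float,
) -> tuple[list[QTLEffectSpec], float]:
    """Scale each QTL's effects so its realized between-cross variance hits its target.

    Returns the scaled specs and the residual polygenic variance
    ``(1 - sum of target fractions) * var_genetic_total`` to pass to the
    phenotype simulator as ``var_poly``.
    """
    scaled = []
    used = 0.0
    for q in qtls:
        if q.target_fraction is None:
            raise ValueError("calibrate_qtl_effects requires target_fraction on every QTL")
        g = qtl_genetic_values(design, probsA, probsB, q)
        v = float(np.var(g))
        if v <= 0:
            raise ValueError(f"QTL at {q.arm}:{q.pos_bp} has zero realized variance")
        s = np.sqrt(q.target_fraction * var_genetic_total / v)
        scaled.append(
            QTLEffectSpec(q.arm, q.pos_bp, q.paternal_effects * s, q.maternal_effects * s,
                          q.target_fraction)
        )
        used += q.target_fraction
    if used > 1.0 + 1e-9:
        raise ValueError("target fractions sum above 1")
    return scaled, max(0.0, (1.0 - used) * var_genetic_total)


@dataclass
class SimulatedPhenotypes:
    """Replicated count phenotypes plus the generative components per cross."""

    table: pd.DataFrame  # cross_id, subpop_combo, block, rep1..3, control_count
    components: pd.DataFrame  # per-cross genetic / block / subpop / polygenic parts


def simulate_phenotypes(
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    qtls: list[QTLEffectSpec],
    mu: float,
    subpop_effect: float = 0.0,
    block_assignment: dict[str, str] | None = None,
    block_effects: dict[str, float] | None = None,
    var_poly: float = 0.0,
    var_env: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    control_mean: float = 120.0,
    control_low_mean: float = 30.0,
    control_low_rate: float = 0.0,
) -> SimulatedPhenotypes:
    """Simulate replicate fecundity counts for every cross.

    Each replicate is mu + subpopulation shift + summed QTL genetic values +
    block effect + a cross-level polygenic deviate (variance ``var_poly``) +
    a replicate deviate (variance ``var_env``), rounded to an integer and
    floored at zero (fecundity is a count).  Control counts are Poisson with
    a small fraction of constitutively low-fecundity crosses.
    """
    rng = np.random.default_rng(seed)
    n = len(design)
    s = (design["subpop_combo"] == "A2B1").to_numpy(dtype=float)
    genetic = np.zeros(n)
    qtl_parts = {}
    for k, q in enumerate(qtls):
        g = qtl_genetic_values(design, probsA, probsB, q)
        qtl_parts[f"qtl{k + 1}"] = g
        genetic += g
    blocks = (
        np.array([block_assignment[c] for c in design["cross_id"]])
        if block_assignment
        else np.array(["B1"] * n)
    )
    beffects = np.array([(block_effects or {}).get(b, 0.0) for b in blocks])
    poly = rng.normal(0.0, np.sqrt(var_poly), size=n) if var_poly > 0 else np.zeros(n)
    mean = mu + subpop_effect * s + genetic + beffects + poly
    noise = (
        rng.normal(0.0, np.sqrt(var_env), size=(n, n_reps))
        if var_env > 0
        else np.zeros((n, n_reps))
    )
    reps = mean[:, None] + noise
    reps = np.maximum(0, np.rint(reps)).astype(int)
    low = rng.random(n) < control_low_rate
    controls = rng.poisson(np.where(low, control_low_mean, control_mean))
    table = pd.DataFrame(
        {
            "cross_id": design["cross_id"],
            "subpop_combo": design["subpop_combo"],
            "block": blocks,
            **{f"rep{r + 1}": reps[:, r] for r in range(n_reps)},
            "control_count": controls,
        }
    )
    components = pd.DataFrame(
        {"cross_id": design["cross_id"], "subpop": subpop_effect * s, **qtl_parts,
         "genetic": genetic, "block": beffects, "polygenic": poly}
    )
    return SimulatedPhenotypes(table=table, components=components)
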