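"""Synthetic plasma-cfDNA cohort generator.

Generates a toy genome, a RepeatMasker-like annotation track, nucleosome-dip
target sites, and benign/malignant fragment cohorts whose class contrasts are
fully controllable: 5' cleavage bias over 4-mers, fragment-length mixture
(malignant shifted shorter), repeat-category sampling rates (benign Alu/SINE
elevated), CNV-like regional depth multipliers, and coverage dips at target
sites.  Because the effects are injected with known sizes, every downstream
feature extractor and the classifier can be validated by parameter recovery.

Fragment generation for one sample:

1. draw a strand and a 5' cut position with probability proportional to the
   cleavage bias of the 4-mer at the cut (reverse-complemented on the minus
   strand);
2. draw a length from the class's mixture of discrete normals;
3. accept with probability proportional to the CNV multiplier, the repeat-rate
   scale of any repeat covering the fragment midpoint, and the dip-thinning
   factor near target sites (Gaussian-shaped depletion);
4. repeat until the requested number of fragments is collected.

All randomness flows from numpy SeedSequence streams, so outputs are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome, GenomeSequence, motif_code, revcomp_code_table
from .io import FragmentSet, IntervalTrack

DIP_SD_BP = 300  # Gaussian width of the site-centred depletion

CATEGORY_SUBFAMILIES = {
    "SINE": (("AluY", 0.4), ("AluS", 0.4), ("AluJ", 0.2)),
    "LINE": (("L1", 0.7), ("L2", 0.3)),
    "LTR": (("ERVL", 0.4), ("ERV1", 0.4), ("Gypsy", 0.2)),
    "Satellite": (("centr", 1.0),),
    "TransposableElement": (
        ("hAT_Charlie", 0.4),
        ("hAT_Tip100", 0.3),
        ("TcMar_Tigger", 0.3),
    ),
    "RNAElement": (("tRNA", 0.5), ("rRNA", 0.3), ("srpRNA", 0.2)),
}

DEFAULT_DENSITIES = {
    "LINE": 0.15,
    "SINE": 0.10,
    "LTR": 0.08,
    "Satellite": 0.02,
    "TransposableElement": 0.03,
    "RNAElement": 0.005,
}

# 4-mers enriched at malignant fragment ends
MALIGNANT_END_MOTIFS = ("CCCA", "CCAA", "CCAT", "CCCT", "CTCC")


@dataclass
class ClassProfile:
    """Generative parameters for one sample class.

    length_mix: (mean bp, sd bp, weight) mixture components (weights sum to 1).
    end_motif_bias: 4-mer -> multiplicative cleavage propensity (missing = 1).
    repeat_rate_scale: repeat category -> multiplicative sampling weight.
    cnv_segments: (chrom, start, end, copy-ratio multiplier) regional depth.
    coverage_dip_depth: fractional midpoint depletion at dip-site centres.
    """

    length_mix: tuple = ((166.0, 9.0, 0.80), (145.0, 12.0, 0.12), (310.0, 18.0, 0.08))
    end_motif_bias: dict = field(default_factory=dict)
    repeat_rate_scale: dict = field(default_factory=dict)
    cnv_segments: tuple = ()
    coverage_dip_depth: float = 0.0

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.length_mix)
        if abs(w - 1.0) > 1e-6:
            raise ValueError("length mixture weights must sum to 1")
        if any(v < 0 for v in self.end_motif_bias.values()):
            raise ValueError("end-motif bias must be >= 0")
        if any(v < 0 for v in self.repeat_rate_scale.values()):
            raise ValueError("repeat rate scales must be >= 0")
        if any(seg[3] < 0 for seg in self.cnv_segments):
            raise ValueError("cnv multipliers must be >= 0")
        if not 0.0 <= self.coverage_dip_depth <= 1.0:
            raise ValueError("coverage_dip_depth must lie in [0, 1]")

    def scaled(self, base: "ClassProfile", alpha: float) -> "ClassProfile":
        """Interpolate/extrapolate this profile's deviation from ``base`` by
        ``alpha`` (0 -> base, 1 -> self, 2 -> doubled effect).  Multiplicative
        parameters scale geometrically, length means arithmetically, the dip
        depth linearly (clipped to [0, 1])."""
        motifs = set(self.end_motif_bias) | set(base.end_motif_bias)
        bias = {}
        for m in motifs:
            b0 = base.end_motif_bias.get(m, 1.0)
            b1 = self.end_motif_bias.get(m, 1.0)
            bias[m] = b0 * (b1 / b0) ** alpha if b0 > 0 else b1 * alpha
        cats = set(self.repeat_rate_scale) | set(base.repeat_rate_scale)
        rep = {}
        for c in cats:
            r0 = base.repeat_rate_scale.get(c, 1.0)
            r1 = self.repeat_rate_scale.get(c, 1.0)
            rep[c] = r0 * (r1 / r0) ** alpha if r0 > 0 else r1 * alpha
        mix = tuple(
            (m0 + alpha * (m1 - m0), s1, w1)
            for (m0, _s0, _w0), (m1, s1, w1) in zip(base.length_mix, self.length_mix)
        )
        cnv = tuple(
            (c, s, e, mult**alpha) for (c, s, e, mult) in self.cnv_segments
        )
        dip = float(
            np.clip(
                base.coverage_dip_depth
                + alpha * (self.coverage_dip_depth - base.coverage_dip_depth),
                0.0,
                1.0,
            )
        )
        return ClassProfile(mix, bias, rep, cnv, dip)


def default_benign_profile() -> ClassProfile:
    """Benign class: neutral cleavage, canonical mono-nucleosomal sizes,
    elevated SINE (Alu) representation, no dips at tumour-open sites."""
    return ClassProfile(repeat_rate_scale={"SINE": 1.3})


def default_malignant_profile(
    genome: Genome | None = None, half_gain: bool = True
) -> ClassProfile:
    """Malignant class: 2x cleavage bias at five 4-mers, sizes shifted 10 bp
    shorter, elevated LTR, a mild CNV gain over half of the last chromosome,
    and a 0.6 midpoint depletion at dip sites."""
    cnv: tuple = ()
    if genome is not None and half_gain:
        last = list(genome)[-1]
        L = genome[last].length
        cnv = ((last, 0, L // 2, 1.25),)
    return ClassProfile(
        length_mix=((156.0, 9.0, 0.80), (135.0, 12.0, 0.12), (300.0, 18.0, 0.08)),
        end_motif_bias={m: 2.0 for m in MALIGNANT_END_MOTIFS},
        repeat_rate_scale={"LTR": 1.2},
        cnv_segments=cnv,
        coverage_dip_depth=0.6,
    )


@dataclass
class CohortSpec:
    """Everything needed to simulate a labelled two-class cohort.

    Genome/annotation/dip-site handles may be left None, in which case
    defaults are generated from the spec's seed.  ``stage_effect_scale`` maps
    tumour stage -> effect multiplier applied to the malignant profile's
    deviation from the benign profile (e.g. {"III": 2.0, "IV": 2.0}).
    """

    n_benign: int = 30
    n_malignant: int = 30
    fragments_per_sample: int = 20_000
    benign_profile: ClassProfile = field(default_factory=default_benign_profile)
    malignant_profile: ClassProfile | None = None
    seed: int = 0
    genome: Genome | None = None
    annotation: IntervalTrack | None = None
    dip_sites: IntervalTrack | None = None
    n_chroms: int = 2
    chrom_length: int = 500_000
    gc_fraction: float = 0.41
    stage_effect_scale: dict | None = None
    stage_probs: dict = field(
        default_factory=lambda: {"I": 0.22, "II": 0.19, "III": 0.53, "IV": 0.06}
    )
    male_fraction: float = 0.60

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("need at least one sample per class")
        if self.fragments_per_sample < 1:
            raise ValueError("fragments_per_sample must be >= 1")


def generate_genome(
    n_chroms: int, chrom_length: int, gc_fraction: float, seed: int
) -> Genome:
    """I.i.d. random genome with P(G) + P(C) = gc_fraction."""
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10000")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0DE]))
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms = []
    for i in range(n_chroms):
        draw = rng.choice(4, size=chrom_length, p=p)
        seq = bases[draw].tobytes().decode("ascii")
        chroms.append(GenomeSequence(f"chr{i + 1}", seq))
    return Genome(chroms)


def generate_annotation(
    genome: Genome,
    category_densities: dict[str, float] | None = None,
    mean_element_length: int = 300,
    seed: int = 0,
) -> IntervalTrack:
    """Place non-overlapping repeat intervals reaching the requested covered
    fraction per category (within ~10% relative); each interval carries a
    subfamily drawn from the category's subfamily list."""
    densities = DEFAULT_DENSITIES if category_densities is None else category_densities
    if sum(densities.values()) > 0.8:
        raise ValueError("total repeat density > 0.8 would thrash placement")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA110]))
    rows = []
    for name, chrom in genome.items():
        L = chrom.length
        occupied = np.zeros(L, dtype=bool)
        for cat in sorted(densities):
            target = densities[cat] * L
            if target <= 0:
                continue
            subs, weights = zip(*CATEGORY_SUBFAMILIES[cat])
            weights = np.asarray(weights) / sum(weights)
            placed = 0
            tries = 0
            max_tries = int(50 * max(target / mean_element_length, 1))
            while placed < target and tries < max_tries:
                tries += 1
                elen = int(
                    np.clip(rng.normal(mean_element_length, mean_element_length / 4), 50, None)
                )
                start = int(rng.integers(0, max(L - elen, 1)))
                if occupied[start : start + elen].any():
                    continue
                occupied[start : start + elen] = True
                sub = subs[int(rng.choice(len(subs), p=weights))]
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((name, start, start + elen, sub, cat, strand))
                placed += elen
    df = pd.DataFrame(rows, columns=IntervalTrack.COLUMNS)
    return IntervalTrack(df if len(df) else pd.DataFrame(columns=IntervalTrack.COLUMNS))


def generate_sites(
    genome: Genome, n_sites: int = 40, seed: int = 0, margin: int = 10_000, width: int = 200
) -> IntervalTrack:
    """Uniformly placed target sites (e.g. open-chromatin centres) away from
    chromosome edges."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x517E]))
    names = list(genome)
    lens = np.array([genome[c].length for c in names], dtype=float)
    rows = []
    for i in range(n_sites):
        ci = int(rng.choice(len(names), p=lens / lens.sum()))
        L = int(lens[ci])
        centre = int(rng.integers(margin, L - margin))
        rows.append(
            (names[ci], centre - width // 2, centre + width // 2, f"site{i}", "site", "+")
        )
    return IntervalTrack(pd.DataFrame(rows, columns=IntervalTrack.COLUMNS))


class _SampleEngine:
    """Precomputed per-(genome, annotation, profile) sampling state, reused
    across samples of the same class."""

    def __init__(
        self,
        genome: Genome,
        annotation: IntervalTrack | None,
        profile: ClassProfile,
        dip_sites: IntervalTrack | None,
        dip_sd: float = DIP_SD_BP,
    ) -> None:
        self.genome = genome
        self.profile = profile
        self.chroms = list(genome)
        rc4 = revcomp_code_table(4)
        bias_vec = np.ones(256)
        for motif, b in profile.end_motif_bias.items():
            bias_vec[motif_code(motif)] = b
        self.cut_plus: dict[str, np.ndarray] = {}
        self.cut_minus: dict[str, np.ndarray] = {}
        self.cum_plus: dict[str, np.ndarray] = {}
        self.cum_minus: dict[str, np.ndarray] = {}
        self.accept: dict[str, np.ndarray] = {}
        totals = []
        for name in self.chroms:
            chrom = genome[name]
            kmers = chrom.kmer_codes(4)
            w = np.where(kmers >= 0, bias_vec[np.clip(kmers, 0, None)], 0.0)
            # plus: cut at p uses 4-mer starting at p (p in [0, L-4])
            wp = np.zeros(chrom.length)
            wp[: len(w)] = w
            # minus: cut at p uses revcomp of 4-mer ending at p (p in [4, L])
            wm = np.zeros(chrom.length + 1)
            rc_w = np.where(kmers >= 0, bias_vec[rc4[np.clip(kmers, 0, None)]], 0.0)
            wm[4 : 4 + len(rc_w)] = rc_w
            self.cut_plus[name] = wp
            self.cut_minus[name] = wm
            self.cum_plus[name] = np.cumsum(wp)
            self.cum_minus[name] = np.cumsum(wm)
            totals.append(self.cum_plus[name][-1] + self.cum_minus[name][-1])
            self.accept[name] = self._acceptance_array(name, annotation, dip_sites, dip_sd)
        totals = np.asarray(totals)
        if totals.sum() <= 0:
            raise ValueError("all cut weights are zero; cannot sample fragments")
        self.chrom_probs = totals / totals.sum()
        self.accept_max = max(float(a.max()) for a in self.accept.values())
        mix = profile.length_mix
        self.mix_means = np.array([m for m, _s, _w in mix])
        self.mix_sds = np.array([s for _m, s, _w in mix])
        self.mix_weights = np.array([w for _m, _s, w in mix])
        self.mix_weights = self.mix_weights / self.mix_weights.sum()

    def _acceptance_array(self, name, annotation, dip_sites, dip_sd) -> np.ndarray:
        L = self.genome[name].length
        acc = np.ones(L)
        for chrom, s, e, mult in self.profile.cnv_segments:
            if chrom == name:
                acc[s:e] *= mult
        if annotation is not None and self.profile.repeat_rate_scale:
            sub = annotation.data[annotation.data["chrom"] == name]
            for iv in sub.itertuples(index=False):
                scale = self.profile.repeat_rate_scale.get(iv.category)
                if scale is not None:
                    acc[iv.start : iv.end] *= scale
        depth = self.profile.coverage_dip_depth
        if dip_sites is not None and depth > 0:
            sub = dip_sites.data[dip_sites.data["chrom"] == name]
            halfspan = int(4 * dip_sd)
            for iv in sub.itertuples(index=False):
                centre = (iv.start + iv.end) // 2
                lo = max(0, centre - halfspan)
                hi = min(L, centre + halfspan)
                d = np.arange(lo, hi) - centre
                acc[lo:hi] *= 1.0 - depth * np.exp(-(d**2) / (2 * dip_sd**2))
        return acc

    def sample(self, n_fragments: int, rng: np.random.Generator) -> pd.DataFrame:
        max_len = float(self.mix_means.max() + 5 * self.mix_sds.max())
        if any(self.genome[c].length <= max_len for c in self.chroms):
            raise ValueError("genome shorter than the maximum fragment length")
        out_chrom: list[np.ndarray] = []
        out_start: list[np.ndarray] = []
        out_end: list[np.ndarray] = []
        out_strand: list[np.ndarray] = []
        collected = 0
        while collected < n_fragments:
            batch = int((n_fragments - collected) * 1.8) + 64
            ci = rng.choice(len(self.chroms), size=batch, p=self.chrom_probs)
            minus = rng.random(batch) < 0.5
            u_pos = rng.random(batch)
            comp = rng.choice(len(self.mix_weights), size=batch, p=self.mix_weights)
            lens = np.rint(
                rng.normal(self.mix_means[comp], self.mix_sds[comp])
            ).astype(np.int64)
            lens = np.clip(lens, 50, None)
            u_acc = rng.random(batch)
            for k, name in enumerate(self.chroms):
                sel = ci == k
                if not sel.any():
                    continue
                cum_p, cum_m = self.cum_plus[name], self.cum_minus[name]
                tot_p, tot_m = cum_p[-1], cum_m[-1]
                m = minus[sel]
                # position of the 5' cut on the chosen strand
                cut = np.empty(int(sel.sum()), dtype=np.int64)
                up = u_pos[sel]
                if (~m).any():
                    cut[~m] = np.searchsorted(cum_p, up[~m] * tot_p, side="right")
                if m.any():
                    cut[m] = np.searchsorted(cum_m, up[m] * tot_m, side="right")
                ln = lens[sel]
                start = np.where(m, cut - ln, cut)
                end = np.where(m, cut, cut + ln)
                L = self.genome[name].length
                ok = (start >= 0) & (end <= L)
                mid = np.clip((start + end) // 2, 0, L - 1)
                ok &= u_acc[sel] < self.accept[name][mid] / self.accept_max
                if not ok.any():
                    continue
                out_chrom.append(np.full(int(ok.sum()), name, dtype=object))
                out_start.append(start[ok])
                out_end.append(end[ok])
                out_strand.append(np.where(m[ok], "-", "+"))
                collected += int(ok.sum())
        df = pd.DataFrame(
            {
                "chrom": np.concatenate(out_chrom),
                "start": np.concatenate(out_start),
                "end": np.concatenate(out_end),
                "strand": np.concatenate(out_strand),
            }
        ).head(n_fragments)
        return df


def simulate_sample(
    genome: Genome,
    annotation: IntervalTrack | None,
    profile: ClassProfile,
    n_fragments: int,
    seed: int,
    dip_sites: IntervalTrack | None = None,
    sample_id: str = "sample",
    _engine: _SampleEngine | None = None,
) -> FragmentSet:
    """Draw one sample's fragments under a class profile (see module docs)."""
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    engine = _engine or _SampleEngine(genome, annotation, profile, dip_sites)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF7A6]))
    df = engine.sample(n_fragments, rng)
    return FragmentSet(sample_id, df, source="simulated")


@dataclass
class SimulatedCohort:
    """Output bundle of :func:`simulate_cohort`: the per-sample fragments and
    metadata plus the generated reference objects needed to extract features."""

    fragment_sets: list
    metadata: pd.DataFrame
    genome: Genome
    annotation: IntervalTrack
    dip_sites: IntervalTrack

    def __iter__(self):
        # allow `frag_sets, metadata = cohort` style unpacking of the two
        # primary outputs
        yield self.fragment_sets
        yield self.metadata


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Simulate the full cohort.

    The returned bundle's metadata carries sample_id, label (0 benign /
    1 malignant), sex, age, and stage (malignant only).
    """
    ss = np.random.SeedSequence([spec.seed, 0xC04027])
    seeds = ss.generate_state(3 + spec.n_benign + spec.n_malignant) % (2**31)
    genome = spec.genome or generate_genome(
        spec.n_chroms, spec.chrom_length, spec.gc_fraction, int(seeds[0])
    )
    annotation = (
        spec.annotation
        if spec.annotation is not None
        else generate_annotation(genome, seed=int(seeds[1]))
    )
    dip_sites = (
        spec.dip_sites
        if spec.dip_sites is not None
        else generate_sites(genome, seed=int(seeds[2]))
    )
    mal_profile = spec.malignant_profile or default_malignant_profile(genome)

    meta_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x3E7A]))
    stages = list(spec.stage_probs)
    stage_p = np.array([spec.stage_probs[s] for s in stages])
    stage_p = stage_p / stage_p.sum()

    fragment_sets: list[FragmentSet] = []
    records = []
    engines: dict[float, _SampleEngine] = {}

    def engine_for(alpha: float | None) -> _SampleEngine:
        # alpha None -> benign; otherwise malignant at that effect scale
        key = -1.0 if alpha is None else float(alpha)
        if key not in engines:
            if alpha is None:
                prof = spec.benign_profile
            elif alpha == 1.0:
                prof = mal_profile
            else:
                prof = mal_profile.scaled(spec.benign_profile, alpha)
            engines[key] = _SampleEngine(genome, annotation, prof, dip_sites)
        return engines[key]

    si = 3
    for i in range(spec.n_benign):
        sid = f"B{i + 1:03d}"
        frags = simulate_sample(
            genome,
            annotation,
            spec.benign_profile,
            spec.fragments_per_sample,
            int(seeds[si]),
            dip_sites,
            sample_id=sid,
            _engine=engine_for(None),
        )
        si += 1
        sex = "M" if meta_rng.random() < spec.male_fraction else "F"
        age = int(np.clip(meta_rng.normal(62, 13), 25, 90))
        fragment_sets.append(frags)
        records.append((sid, 0, sex, age, ""))
    for i in range(spec.n_malignant):
        sid = f"M{i + 1:03d}"
        stage = stages[int(meta_rng.choice(len(stages), p=stage_p))]
        alpha = 1.0
        if spec.stage_effect_scale:
            alpha = float(spec.stage_effect_scale.get(stage, 1.0))
        frags = simulate_sample(
            genome,
            annotation,
            mal_profile,
            spec.fragments_per_sample,
            int(seeds[si]),
            dip_sites,
            sample_id=sid,
            _engine=engine_for(alpha),
        )
        si += 1
        sex = "M" if meta_rng.random() < spec.male_fraction else "F"
        age = int(np.clip(meta_rng.normal(63, 12), 25, 90))
        fragment_sets.append(frags)
        records.append((sid, 1, sex, age, stage))
    metadata = pd.DataFrame(
        records, columns=["sample_id", "label", "sex", "age", "stage"]
    ).set_index("sample_id")
    return SimulatedCohort(fragment_sets, metadata, genome, annotation, dip_sites)
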