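"""Synthetic proximity-labeling studies with planted ground truth.

Generates everything the downstream stages consume — abundance matrices,
annotation tables, peak sets and signal tracks — with known planted
structure, so parameter recovery and error calibration are testable without
external data.

The abundance generator emulates a five-genotype TurboID design: a
no-ligase ``control``, promiscuous ``turboid`` alone (with an optional
chromatin-biased background preference), a DNA-adjacent ``dcas9`` control,
and N-/C-terminally tagged bait fusions ``nt_kdm5``/``ct_kdm5``; two
experiment batches (the dcas9 control only exists in the second), replicate
noise, a batch shift, and intensity-dependent (MNAR) missingness from a
logistic dropout curve. Planted interactors are nuclear and come in three
classes — shared between termini, NT-only and CT-only — with a configurable
log2 effect size in the corresponding bait condition(s).

All draws in each generator come from one generator seeded from the
config; identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import AbundanceMatrix, GeneList, OrthologMap
from .errors import ConfigurationError, ValidationError
from .genome import ChromSizes, PeakSet, SignalTrack

CONDITIONS = ("control", "turboid", "dcas9", "nt_kdm5", "ct_kdm5")
EXP1_CONDITIONS = ("control", "turboid", "nt_kdm5", "ct_kdm5")
EXP2_CONDITIONS = CONDITIONS

LABEL_SHARED = "shared"
LABEL_NT_ONLY = "nt_only"
LABEL_CT_ONLY = "ct_only"
LABEL_BACKGROUND = "background_biased"
LABEL_NULL = "null"
PLANTED_LABELS = (LABEL_SHARED, LABEL_NT_ONLY, LABEL_CT_ONLY)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Parameters of a simulated two-experiment proximity-labeling study.

    Defaults emulate the scale of a head-tissue TurboID screen: ~1500
    proteins identified, about a third nuclear, ~90 genuine bait-proximal
    proteins (mostly shared between the two fusion termini), a 2 log2-unit
    mean enrichment, quadruplicate and triplicate pulldowns, and a steep
    logistic detection-dropout curve giving roughly 6% missing values,
    concentrated in the lowest-abundance proteins.
    """

    n_proteins: int = 1500
    frac_nuclear: float = 0.35
    n_true_shared: int = 60
    n_true_nt_only: int = 15
    n_true_ct_only: int = 15
    effect_size_log2: float = 2.0
    replicate_sd_log2: float = 0.5
    batch_shift_log2: float = 0.5
    baseline_mean_log2: float = 20.0
    baseline_sd_log2: float = 2.0
    missingness_midpoint_log2: float = 16.5
    missingness_slope: float = 1.5
    replicates_exp1: int = 4
    replicates_exp2: int = 3
    background_bias_strength: float = 1.5
    n_background_biased: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigurationError("n_proteins must be positive")
        if not (0 <= self.frac_nuclear <= 1):
            raise ConfigurationError("frac_nuclear must lie in [0, 1]")
        for name in ("n_true_shared", "n_true_nt_only", "n_true_ct_only",
                     "n_background_biased"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("replicates_exp1", "replicates_exp2"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("replicate_sd_log2", "baseline_sd_log2"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.background_bias_strength < 0:
            raise ConfigurationError("background_bias_strength must be >= 0")
        n_nuclear = int(round(self.frac_nuclear * self.n_proteins))
        n_planted = (self.n_true_shared + self.n_true_nt_only
                     + self.n_true_ct_only)
        if n_planted > n_nuclear:
            raise ConfigurationError(
                f"{n_planted} planted interactors exceed the {n_nuclear} "
                "nuclear proteins (planted interactors are nuclear)"
            )

    @property
    def n_nuclear(self) -> int:
        return int(round(self.frac_nuclear * self.n_proteins))


@dataclass
class PlantedTruth:
    """The generator's record of what was planted.

    ``labels`` maps every protein id to exactly one class label; ``effects``
    holds the true per-condition log2 effect for every protein (zero for
    nulls); ``nuclear`` is the nuclear subset.
    """

    labels: dict[str, str]
    effects: pd.DataFrame
    nuclear: frozenset[str]
    seed: int
    config: dict = field(default_factory=dict)

    def members(self, label: str) -> tuple[str, ...]:
        return tuple(p for p, lab in self.labels.items() if lab == label)

    @property
    def planted_interactors(self) -> tuple[str, ...]:
        return tuple(p for p, lab in self.labels.items()
                     if lab in PLANTED_LABELS)


def generate_abundance_study(config: SyntheticStudyConfig
                             ) -> tuple[AbundanceMatrix, PlantedTruth]:
    """Simulate the raw abundance matrix and its planted truth.

    In log2 space, the intensity of protein *i* in sample *s* is
    ``baseline_i + condition_effect + batch_shift + Normal(0, replicate_sd)``;
    values are exponentiated to the raw scale and each cell is then masked
    missing with probability
    ``logistic(missingness_slope * (missingness_midpoint - log2 intensity))``,
    so low-intensity measurements drop out preferentially.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = [f"P{i:05d}" for i in range(n)]

    nuclear_idx = np.sort(rng.choice(n, size=config.n_nuclear, replace=False))
    shuffled = rng.permutation(nuclear_idx)
    n_sh, n_nt, n_ct = (config.n_true_shared, config.n_true_nt_only,
                        config.n_true_ct_only)
    shared_idx = shuffled[:n_sh]
    nt_idx = shuffled[n_sh:n_sh + n_nt]
    ct_idx = shuffled[n_sh + n_nt:n_sh + n_nt + n_ct]
    rest_nuclear = shuffled[n_sh + n_nt + n_ct:]
    n_bg = min(config.n_background_biased, len(rest_nuclear))
    bg_idx = rest_nuclear[:n_bg]

    labels = {p: LABEL_NULL for p in proteins}
    for i in shared_idx:
        labels[proteins[i]] = LABEL_SHARED
    for i in nt_idx:
        labels[proteins[i]] = LABEL_NT_ONLY
    for i in ct_idx:
        labels[proteins[i]] = LABEL_CT_ONLY
    for i in bg_idx:
        labels[proteins[i]] = LABEL_BACKGROUND

    effects = pd.DataFrame(0.0, index=pd.Index(proteins, name="protein_id"),
                           columns=list(CONDITIONS))
    eff = config.effect_size_log2
    effects.iloc[shared_idx, effects.columns.get_loc("nt_kdm5")] = eff
    effects.iloc[shared_idx, effects.columns.get_loc("ct_kdm5")] = eff
    effects.iloc[nt_idx, effects.columns.get_loc("nt_kdm5")] = eff
    effects.iloc[ct_idx, effects.columns.get_loc("ct_kdm5")] = eff
    effects.iloc[bg_idx, effects.columns.get_loc("turboid")] = \
        config.background_bias_strength

    baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, n)

    samples: list[tuple[str, str, str, int]] = []   # id, condition, exp, rep
    for cond in EXP1_CONDITIONS:
        for rep in range(1, config.replicates_exp1 + 1):
            samples.append((f"{cond}_exp1_r{rep}", cond, "exp1", rep))
    for cond in EXP2_CONDITIONS:
        for rep in range(1, config.replicates_exp2 + 1):
            samples.append((f"{cond}_exp2_r{rep}", cond, "exp2", rep))

    log2_matrix = np.empty((n, len(samples)))
    for j, (_, cond, exp, _) in enumerate(samples):
        shift = config.batch_shift_log2 if exp == "exp2" else 0.0
        noise = rng.normal(0.0, config.replicate_sd_log2, n)
        log2_matrix[:, j] = (baseline + effects[cond].to_numpy()
                             + shift + noise)

    p_missing = expit(config.missingness_slope
                      * (config.missingness_midpoint_log2 - log2_matrix))
    missing = rng.random(log2_matrix.shape) < p_missing

    raw = np.power(2.0, log2_matrix)
    raw[missing] = np.nan
    values = pd.DataFrame(raw, index=pd.Index(proteins, name="protein_id"),
                          columns=[s[0] for s in samples])
    metadata = pd.DataFrame(
        {"condition": [s[1] for s in samples],
         "experiment": [s[2] for s in samples],
         "replicate": [s[3] for s in samples]},
        index=pd.Index([s[0] for s in samples], name="sample_id"),
    )
    truth = PlantedTruth(
        labels=labels, effects=effects,
        nuclear=frozenset(proteins[i] for i in nuclear_idx),
        seed=config.seed, config=asdict(config),
    )
    return AbundanceMatrix(values=values, metadata=metadata), truth


@dataclass
class AnnotationBundle:
    """Synthetic annotation tables tied to one planted truth."""

    nuclear: GeneList
    known: GeneList
    known_planted: tuple[str, ...]
    orthologs: OrthologMap
    universe: GeneList              # all human-side ids (orthologs + fillers)
    disease: dict[str, GeneList]
    planted_disease_overlap: dict[str, tuple[str, ...]]  # list -> human ids


def generate_annotation_tables(config: SyntheticStudyConfig,
                               truth: PlantedTruth,
                               n_known_planted: int = 7,
                               n_known_decoys: int = 8,
                               disease_overlap: dict[str, int] | None = None,
                               disease_list_size: int = 150,
                               disease_shared: int = 14
                               ) -> AnnotationBundle:
    """Nuclear list, known-interactor list, ortholog table and disease lists.

    The known-interactor list mixes ``n_known_planted`` genuinely planted
    interactors with ``n_known_decoys`` nuclear decoys, emulating a
    literature-curated complex list of which only part is recoverable in
    any one screen. Every fly protein gets one high-confidence primary
    human ortholog plus occasional extra paralogs with random scores;
    planted interactors' primaries always pass the score > 8 threshold.
    Disease lists contain a planted number of interactor orthologs
    (defaults: 12 for the first list, 10 for the second, sharing
    ``disease_shared`` members) topped up with filler ids disjoint from
    every ortholog target, so the planted overlap count is exact.
    """
    rng = np.random.default_rng([config.seed, 101])
    planted = list(truth.planted_interactors)
    if n_known_planted > len(planted):
        raise ValidationError(
            f"requested {n_known_planted} known planted interactors but "
            f"only {len(planted)} were planted"
        )
    nuclear_sorted = sorted(truth.nuclear)
    nuclear_list = GeneList(name="nuclear", members=tuple(nuclear_sorted))

    known_planted = tuple(rng.choice(planted, size=n_known_planted,
                                     replace=False))
    decoy_pool = sorted(set(nuclear_sorted) - set(planted))
    if n_known_decoys > len(decoy_pool):
        raise ValidationError("not enough non-planted nuclear proteins for decoys")
    decoys = tuple(rng.choice(decoy_pool, size=n_known_decoys, replace=False))
    known = GeneList(name="known_interactors",
                     members=tuple(sorted(known_planted + decoys)))

    # ortholog table: one confident primary per protein, extra paralogs ~30%
    proteins = list(truth.effects.index)
    planted_set = set(planted)
    records = []
    primary_of: dict[str, str] = {}
    for pid in proteins:
        primary = f"H_{pid}_1"
        primary_of[pid] = primary
        if pid in planted_set:
            score = int(rng.integers(9, 16))
        else:
            score = int(rng.integers(4, 16))
        records.append((pid, primary, score))
        n_extra = int(rng.choice([0, 0, 0, 1, 2]))
        for j in range(n_extra):
            records.append((pid, f"H_{pid}_{j + 2}", int(rng.integers(1, 16))))
    orthologs = OrthologMap(records=pd.DataFrame(
        records, columns=["source_id", "target_id", "score"]))

    all_targets = list(orthologs.records["target_id"])
    planted_orth = [primary_of[p] for p in planted]
    if disease_overlap is None:
        # default planted overlaps echo the scale of curated autism /
        # developmental-disorder lists against an 80-90 protein interactome,
        # capped by the number of planted interactors in scaled-down studies
        disease_overlap = {"sfari_like": min(26, len(planted_orth)),
                           "dbd_like": min(24, len(planted_orth))}
    names = list(disease_overlap)
    needed = max(disease_overlap.values(), default=0)
    if needed > len(planted_orth):
        raise ValidationError(
            f"planted disease overlap {needed} exceeds the "
            f"{len(planted_orth)} planted interactors"
        )
    first_pick: list[str] = []
    picked: dict[str, tuple[str, ...]] = {}
    for i, name in enumerate(names):
        k = disease_overlap[name]
        if i == 0:
            first_pick = list(rng.choice(planted_orth, size=k, replace=False))
            picked[name] = tuple(first_pick)
        else:
            n_shared = min(disease_shared, k, len(first_pick))
            shared_members = first_pick[:n_shared]
            pool = sorted(set(planted_orth) - set(first_pick))
            extra_n = min(k - n_shared, len(pool))
            extra = list(rng.choice(pool, size=extra_n, replace=False)) \
                if extra_n else []
            picked[name] = tuple(shared_members + extra)

    filler_count = sum(max(disease_list_size - len(picked[n]), 0)
                       for n in names)
    fillers = [f"HD_{i:05d}" for i in range(filler_count)]
    filler_iter = iter(fillers)
    disease: dict[str, GeneList] = {}
    for name in names:
        members = list(picked[name])
        members += [next(filler_iter)
                    for _ in range(disease_list_size - len(members))]
        scores = {m: float(rng.integers(1, 4)) for m in members}
        disease[name] = GeneList(name=name, members=tuple(members),
                                 scores=scores)

    universe = GeneList(name="universe",
                        members=tuple(dict.fromkeys(all_targets + fillers)))
    return AnnotationBundle(
        nuclear=nuclear_list, known=known, known_planted=known_planted,
        orthologs=orthologs, universe=universe, disease=disease,
        planted_disease_overlap=picked,
    )


# ---------------------------------------------------------------------------
# genomic generators

PEAK_MODES = ("coincident", "flanking_bimodal", "independent")


def generate_peak_sets(chrom_sizes: ChromSizes, n_query: int, n_target: int,
                       mode: str, offset_sd: float = 0.0,
                       seed: int | None = None, query_width: int = 200,
                       target_width: int = 200, flank_offset: int = 500
                       ) -> tuple[PeakSet, PeakSet]:
    """Query/target peak pairs with planted co-localization structure.

    ``coincident`` centers each query peak on a target center plus
    Normal(0, offset_sd) jitter; ``flanking_bimodal`` displaces it by a
    fixed ``flank_offset`` with random sign (a bait binding the two
    divergent promoters flanking a factor's site); ``independent`` places
    both sets uniformly. All intervals are clipped to their chromosome and
    are 0-based half-open.
    """
    if mode not in PEAK_MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; choose from {PEAK_MODES}")
    if n_query <= 0 or n_target <= 0:
        raise ConfigurationError("n_query and n_target must be positive")
    rng = np.random.default_rng(seed)
    names = [c for c, L in chrom_sizes.items()]

    def place_uniform(n_peaks: int, width: int) -> tuple[np.ndarray, np.ndarray]:
        eligible = [(c, chrom_sizes[c]) for c in names if chrom_sizes[c] >= width]
        if not eligible:
            raise ConfigurationError(
                f"no chromosome can fit a peak of width {width}"
            )
        slots = np.array([L - width + 1 for _, L in eligible], dtype=float)
        probs = slots / slots.sum()
        chosen = rng.choice(len(eligible), size=n_peaks, p=probs)
        chroms = np.array([eligible[i][0] for i in chosen], dtype=object)
        highs = np.array([eligible[i][1] - width + 1 for i in chosen])
        starts = rng.integers(0, highs)
        return chroms, starts

    t_chroms, t_starts = place_uniform(n_target, target_width)
    target = PeakSet(t_chroms, t_starts, t_starts + target_width, label="target")

    if mode == "independent":
        q_chroms, q_starts = place_uniform(n_query, query_width)
    else:
        assoc = np.arange(n_query) % n_target
        centers = target.midpoints[assoc]
        q_chroms = t_chroms[assoc].copy()
        if mode == "coincident":
            shift = np.round(rng.normal(0.0, offset_sd, n_query)).astype(np.int64)
        else:
            sign = rng.choice([-1, 1], size=n_query)
            shift = sign * int(flank_offset)
        q_starts = centers + shift - query_width // 2
        limits = np.array([chrom_sizes[str(c)] for c in q_chroms])
        if (limits < query_width).any():
            raise ConfigurationError(
                f"query width {query_width} does not fit every chromosome used"
            )
        q_starts = np.clip(q_starts, 0, limits - query_width)
    query = PeakSet(q_chroms, q_starts, q_starts + query_width, label="query")
    return query, target


def generate_signal_track(peaks: PeakSet, peak_height: float,
                          background: float, chrom_sizes: ChromSizes
                          ) -> SignalTrack:
    """Piecewise-constant track: ``background`` everywhere, ``peak_height``
    on peak intervals (overlapping peaks take the maximum, which for a
    single height equals their union)."""
    if not (peak_height >= background >= 0):
        raise ConfigurationError(
            f"need peak_height >= background >= 0, got "
            f"{peak_height} and {background}"
        )
    peaks.validate_against(chrom_sizes)
    by_chrom = peaks.by_chrom()
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, length in chrom_sizes.items():
        segs: list[tuple[int, int, float]] = []
        pos = 0
        if chrom in by_chrom:
            s, e = by_chrom[chrom]
            # merge union of peak intervals (equal heights -> max == union)
            from .overlap import _merge_sorted
            ms, me = _merge_sorted(s, np.minimum(e, length))
            for a, b in zip(ms, me):
                if a > pos:
                    segs.append((pos, int(a), background))
                segs.append((int(a), int(b), peak_height))
                pos = int(b)
        if pos < length:
            segs.append((pos, length, background))
        arr = np.array(segs, dtype=float)
        data[chrom] = (arr[:, 0].astype(np.int64),
                       arr[:, 1].astype(np.int64), arr[:, 2])
    return SignalTrack(data=data)
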