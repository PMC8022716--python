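"""Candidate Chi-motif calls: overrepresentation x polarity, de novo
scans, false-positive estimation, aggregation, and GC comparisons.

A motif is a candidate in a species when its core-genome z-score
clears the per-order threshold under at least K of the Markov model
orders AND (in polarized mode) its genomic occurrences are
significantly strand-biased.  Defaults: z >= 4 for every order, K = 3,
polarity alpha = 0.001.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import _codes
from .polarity import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_PER_STRAND,
    OccurrenceSet,
    PolarityResult,
    find_occurrences_many,
    polarity_test,
)
from .words import (
    DEFAULT_B,
    DEFAULT_ORDERS,
    WordStatistic,
    _as_sequences,
    _null_count_moments,
    expected_count,
    fit_markov,
)

__all__ = [
    "DetectionConfig",
    "MotifCall",
    "detect_candidates",
    "detect_unpolarized",
    "denovo_scan",
    "aggregate_across_species",
    "AggregateResult",
    "estimate_fpr",
    "FprEstimate",
    "gc_group_comparison",
    "GcComparison",
    "calls_to_records",
]

logger = logging.getLogger("chiscan")

DEFAULT_Z_THRESHOLD = 4.0


@dataclass
class DetectionConfig:
    """Thresholds and knobs of the candidate-calling criterion."""

    z_thresholds: dict[int, float] = field(
        default_factory=lambda: {o: DEFAULT_Z_THRESHOLD for o in DEFAULT_ORDERS}
    )
    min_models: int = 3
    alpha: float = DEFAULT_ALPHA
    min_per_strand: int = DEFAULT_MIN_PER_STRAND
    mode: str = "polarized"
    bootstrap_B: int = DEFAULT_B
    seed: int = 0
    replicon_scope: str = "largest"  # or "all"

    def __post_init__(self) -> None:
        if not self.z_thresholds:
            raise ValueError("z_thresholds must name at least one order")
        if not (1 <= self.min_models <= len(self.z_thresholds)):
            raise ValueError(
                "min_models must be between 1 and the number of orders"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.mode not in ("polarized", "unpolarized"):
            raise ValueError("mode must be 'polarized' or 'unpolarized'")
        if self.replicon_scope not in ("largest", "all"):
            raise ValueError("replicon_scope must be 'largest' or 'all'")

    @property
    def orders(self) -> list[int]:
        return sorted(self.z_thresholds)


@dataclass
class MotifCall:
    """Per-species, per-motif verdict."""

    species_id: str
    motif: str
    stats: list[WordStatistic]
    models_passed: int
    polarity: PolarityResult
    candidate: bool
    mode: str


def _score_words_batch(
    seqs: list[str],
    words: list[str],
    config: DetectionConfig,
) -> dict[str, list[WordStatistic]]:
    """Score every word under every configured order on a core.

    One model fit and one batched bootstrap pass (all 4^h counts per
    replicate) per order; words share replicates, which only tightens
    the comparison across words.
    """
    h = len(words[0])
    arrays = [_codes.encode(s) for s in seqs]
    lengths = [a.size for a in arrays]
    concat = _codes.concat_with_breaks(arrays)
    obs_all = _codes.kmer_count_array(concat, h)
    widx = [_codes.word_to_index(_codes.encode_word(w)) for w in words]
    out: dict[str, list[WordStatistic]] = {w: [] for w in words}
    ss = np.random.SeedSequence(config.seed).spawn(len(config.orders))
    for order, child in zip(config.orders, ss):
        usable = concat.size >= order + 1 and max(lengths, default=0) > order
        model = None
        if usable:
            try:
                model = fit_markov(arrays, order)
            except ValueError:
                model = None
        if model is None:
            for w in words:
                out[w].append(
                    WordStatistic(w, order, 0, None, None, None, False)
                )
            continue
        rng = np.random.default_rng(child)
        _, sd_all = _null_count_moments(
            model, h, lengths, config.bootstrap_B, rng
        )
        for w, wi in zip(words, widx):
            observed = int(obs_all[wi])
            exp = expected_count(model, w)
            sd = float(sd_all[wi])
            if exp is None or sd == 0.0:
                out[w].append(
                    WordStatistic(
                        w, order, observed, exp, sd if exp is not None else None,
                        None, False,
                    )
                )
            else:
                z = (observed - exp) / sd
                out[w].append(
                    WordStatistic(w, order, observed, exp, sd, float(z), True)
                )
    return out


def _polarity_replicons(genomes, scope: str):
    if not genomes:
        return []
    if scope == "largest":
        return [max(genomes, key=lambda g: len(g.sequence))]
    return list(genomes)


def _species_id_of(core, genomes) -> str:
    sid = getattr(core, "species_id", None)
    if sid:
        return sid
    if genomes:
        return genomes[0].species_id
    return "species"


def detect_candidates(
    core,
    genomes,
    motifs,
    config: DetectionConfig | None = None,
) -> list[MotifCall]:
    """Call candidate motifs for one species.

    Overrepresentation is computed on the core gene sequences; the
    polarity test runs on whole replicons (largest by default, all
    poolable via config).  Every motif's call is returned, candidates
    and non-candidates alike, sorted by species then motif.
    """
    config = config or DetectionConfig()
    words = sorted(set(motifs))
    if not words:
        return []
    seqs = _as_sequences(core)
    species = _species_id_of(core, genomes)
    if not seqs or sum(len(s) for s in seqs) < len(words[0]):
        warnings.warn(f"empty core for {species}: motifs non-evaluable")
        stats_by_word = {
            w: [
                WordStatistic(w, o, 0, None, None, None, False)
                for o in config.orders
            ]
            for w in words
        }
    else:
        stats_by_word = _score_words_batch(seqs, words, config)

    replicons = _polarity_replicons(genomes, config.replicon_scope)
    occ_by_motif: dict[str, list[OccurrenceSet]] = {w: [] for w in words}
    for rep in replicons:
        found = find_occurrences_many(rep, words)
        for w in words:
            occ_by_motif[w].append(found[w])

    calls: list[MotifCall] = []
    for w in words:
        stats_list = stats_by_word[w]
        passed = sum(
            1
            for st in stats_list
            if st.passes(config.z_thresholds[st.model_order])
        )
        pooled = OccurrenceSet(
            motif=w,
            replicon_id=";".join(o.replicon_id for o in occ_by_motif[w])
            or "",
            occurrences=[
                occ
                for oset in occ_by_motif[w]
                for occ in oset.occurrences
            ],
        )
        pol = polarity_test(
            pooled, alpha=config.alpha, min_per_strand=config.min_per_strand
        )
        if config.mode == "polarized":
            candidate = passed >= config.min_models and pol.polarized
        else:
            candidate = passed >= config.min_models
        calls.append(
            MotifCall(
                species_id=species,
                motif=w,
                stats=stats_list,
                models_passed=passed,
                polarity=pol,
                candidate=candidate,
                mode=config.mode,
            )
        )
    logger.info(
        "species %s: %d/%d candidate motifs",
        species,
        sum(c.candidate for c in calls),
        len(calls),
    )
    return sorted(calls, key=lambda c: (c.species_id, c.motif))


def detect_unpolarized(core, genomes, motifs, config=None) -> list[MotifCall]:
    """Same criterion with the polarity clause removed (still reported)."""
    config = config or DetectionConfig()
    return detect_candidates(
        core, genomes, motifs, replace(config, mode="unpolarized")
    )


def denovo_scan(
    core,
    config: DetectionConfig | None = None,
    word_length: int = 8,
    full_table: bool = False,
) -> pd.DataFrame:
    """Score ALL 4^h words of length h on a core under every order.

    Uses the batched bootstrap (each replicate yields counts for every
    word at once).  Returns words meeting the per-order thresholds in
    >= min_models orders — or the full score table — sorted by
    models_passed then mean z, descending.
    """
    config = config or DetectionConfig()
    seqs = _as_sequences(core)
    if not seqs:
        raise ValueError("empty core")
    h = word_length
    arrays = [_codes.encode(s) for s in seqs]
    lengths = [a.size for a in arrays]
    concat = _codes.concat_with_breaks(arrays)
    obs = _codes.kmer_count_array(concat, h).astype(float)
    n_words = 4**h
    W = np.arange(n_words, dtype=np.int64)
    z_cols: dict[str, np.ndarray] = {}
    passed = np.zeros(n_words, dtype=np.int64)
    zsum = np.zeros(n_words)
    zn = np.zeros(n_words)
    ss = np.random.SeedSequence(config.seed).spawn(len(config.orders))
    for order, child in zip(config.orders, ss):
        model = fit_markov(arrays, order)
        exp, ok = _expected_all_words(model, h, W)
        rng = np.random.default_rng(child)
        _, sd = _null_count_moments(model, h, lengths, config.bootstrap_B, rng)
        evaluable = ok & (sd > 0)
        z = np.full(n_words, np.nan)
        z[evaluable] = (obs[evaluable] - exp[evaluable]) / sd[evaluable]
        z_cols[f"z_m{order}"] = z
        thr = config.z_thresholds[order]
        hit = evaluable & (z >= thr)
        passed += hit
        zsum += np.where(np.isfinite(z), z, 0.0)
        zn += np.isfinite(z)
    mean_z = np.where(zn > 0, zsum / np.maximum(zn, 1), np.nan)
    df = pd.DataFrame(
        {
            "motif": [_codes.index_to_word(i, h) for i in range(n_words)],
            "observed": obs.astype(int),
            "models_passed": passed,
            "mean_z": mean_z,
            **z_cols,
        }
    )
    if not full_table:
        df = df[df["models_passed"] >= config.min_models]
    df = df.sort_values(
        ["models_passed", "mean_z", "motif"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df


def _expected_all_words(model, h: int, W: np.ndarray):
    """Vectorized plug-in expectation for every length-h word."""
    m = model.order
    if h < m + 1:
        raise ValueError("word length below order + 1")
    num = np.ones(W.size)
    for j in range(h - m):
        shift = 2 * (h - (j + m + 1))
        sub = (W >> shift) & (4 ** (m + 1) - 1)
        num *= model.counts_m1[sub]
    den = np.ones(W.size)
    ok = np.ones(W.size, dtype=bool)
    for j in range(1, h - m):
        if m == 0:
            factor = np.full(W.size, float(model.counts_m[0]))
        else:
            shift = 2 * (h - (j + m))
            sub = (W >> shift) & (4**m - 1)
            factor = model.counts_m[sub].astype(float)
        ok &= factor > 0
        den *= np.where(factor > 0, factor, 1.0)
    return num / den, ok


@dataclass
class AggregateResult:
    """Cross-species view of candidate calls."""

    per_motif: pd.DataFrame  # motif, n_species_candidate, species
    per_species: dict[str, list[str]]
    fraction_species_with_candidate: float


def aggregate_across_species(calls: list[MotifCall]) -> AggregateResult:
    """Count species (not calls) per candidate motif.

    A species with several candidate motifs contributes to each; the
    per-species lists and the fraction of species with >= 1 candidate
    are emitted alongside.
    """
    if not calls:
        raise ValueError("need calls from at least one species")
    species = sorted({c.species_id for c in calls})
    per_species: dict[str, list[str]] = {sp: [] for sp in species}
    for c in calls:
        if c.candidate:
            per_species[c.species_id].append(c.motif)
    per_species = {sp: sorted(set(ms)) for sp, ms in per_species.items()}
    motif_species: dict[str, set[str]] = {}
    for sp, ms in per_species.items():
        for m in ms:
            motif_species.setdefault(m, set()).add(sp)
    rows = [
        (m, len(sps), ";".join(sorted(sps)))
        for m, sps in sorted(
            motif_species.items(), key=lambda kv: (-len(kv[1]), kv[0])
        )
    ]
    per_motif = pd.DataFrame(
        rows, columns=["motif", "n_species_candidate", "species"]
    )
    frac = sum(1 for ms in per_species.values() if ms) / len(species)
    return AggregateResult(
        per_motif=per_motif,
        per_species=per_species,
        fraction_species_with_candidate=frac,
    )


@dataclass
class FprEstimate:
    """False-positive rates on a labeled outgroup, both denominators."""

    per_species_rate: float
    per_test_rate: float
    n_outgroup_species: int
    n_outgroup_with_candidate: int
    n_tests: int
    n_candidate_tests: int


def estimate_fpr(
    calls_by_species: dict[str, list[MotifCall]],
    outgroup_labels: set[str],
) -> FprEstimate:
    """FPR on species not expected to carry the motifs.

    per-species: outgroup species with >= 1 candidate / outgroup
    species; per-test: candidate motif-species pairs / pairs evaluated.
    Both are reported because either denominator is defensible.
    """
    if not outgroup_labels:
        raise ValueError("outgroup must be non-empty")
    missing = set(outgroup_labels) - set(calls_by_species)
    if missing:
        raise KeyError(f"outgroup species without calls: {sorted(missing)}")
    n_sp = len(outgroup_labels)
    n_sp_pos = 0
    n_tests = 0
    n_pos = 0
    for sp in sorted(outgroup_labels):
        calls = calls_by_species[sp]
        n_tests += len(calls)
        k = sum(1 for c in calls if c.candidate)
        n_pos += k
        if k:
            n_sp_pos += 1
    return FprEstimate(
        per_species_rate=n_sp_pos / n_sp,
        per_test_rate=(n_pos / n_tests) if n_tests else 0.0,
        n_outgroup_species=n_sp,
        n_outgroup_with_candidate=n_sp_pos,
        n_tests=n_tests,
        n_candidate_tests=n_pos,
    )


@dataclass
class GcComparison:
    """Genomic GC of species with vs without candidate motifs."""

    skipped: bool
    message: str = ""
    n_with: int = 0
    n_without: int = 0
    mean_with: float = float("nan")
    mean_without: float = float("nan")
    median_with: float = float("nan")
    median_without: float = float("nan")
    p_value: float = float("nan")


def gc_group_comparison(
    species_table: dict[str, tuple[float, bool]]
) -> GcComparison:
    """Two-sided rank-sum comparison of GC between candidate groups."""
    gc_with = [gc for gc, has in species_table.values() if has]
    gc_without = [gc for gc, has in species_table.values() if not has]
    if not gc_with or not gc_without:
        return GcComparison(
            skipped=True,
            message="one group is empty; comparison skipped",
            n_with=len(gc_with),
            n_without=len(gc_without),
        )
    x = np.asarray(gc_with, dtype=float)
    y = np.asarray(gc_without, dtype=float)
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size != pooled.size
    use_exact = min(x.size, y.size) <= 25 and not ties
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return GcComparison(
        skipped=False,
        n_with=x.size,
        n_without=y.size,
        mean_with=float(x.mean()),
        mean_without=float(y.mean()),
        median_with=float(np.median(x)),
        median_without=float(np.median(y)),
        p_value=float(res.pvalue),
    )


def calls_to_records(calls: list[MotifCall]) -> list[dict]:
    """Flatten calls into rows for write_results_table."""
    rows = []
    for c in calls:
        row = {
            "species": c.species_id,
            "motif": c.motif,
            "models_passed": c.models_passed,
            "candidate": c.candidate,
            "mode": c.mode,
            "n_plus": c.polarity.n_plus,
            "n_minus": c.polarity.n_minus,
            "polarity_p": c.polarity.p_value,
            "polarized": c.polarity.polarized,
            "indeterminate": c.polarity.indeterminate,
        }
        for st in c.stats:
            row[f"z_m{st.model_order}"] = (
                st.z if st.evaluable else float("nan")
            )
        rows.append(row)
    return rows
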