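"""Experimental design: eligibility, species windows, splits and schedules.

The protocol emulated here builds, per selected taxon (normally an order),
a set of independent *runs*.  Each run selects a window of taxonomically
adjacent species, holds out a fixed test set, and derives a nested sequence
of *tasks*: training/validation subsets that shrink by one quarter at each
step, so that a recognition model trained per task traces out a learning
curve over training-set size.

Key constants (all overridable):

* eligibility threshold — 220 image-bearing observations per species,
  leaving at least 20 test observations beside the 200-observation base task;
* window — 17 consecutive species from the taxonomically sorted list;
* base task — 200 observations per species, split 9:1 train:validation;
* reduction — discard ``floor(n/4)`` observations per step (exactly 25%
  when divisible by 4, slightly less otherwise) while at least 10
  observations per species remain, giving the 11-task schedule
  200, 150, 113, 85, 64, 48, 36, 27, 21, 16, 12;
* runs — 5 per taxon.

All randomness flows from explicit integer seeds which are recorded in the
run manifests, so every run can be regenerated bit-for-bit.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dwc_io import RANKS, ObservationRecord

#: candidate grouping ranks, coarsest first (species itself is not a grouping)
GROUPING_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

DEFAULT_THRESHOLD = 220
DEFAULT_WINDOW = 17
DEFAULT_BASE = 200
DEFAULT_STOP_MIN = 10
DEFAULT_N_RUNS = 5
DEFAULT_MIN_TAXA = 12

#: minimum held-out observations per species beyond the base task
MIN_TEST = 20


@dataclass(frozen=True)
class EligibilityReport:
    """How many threshold-qualifying species each taxon at a rank offers."""

    rank: str
    taxa: Mapping[str, int]          # taxon -> count of eligible species
    min_species: int                 # min over the taxa considered
    n_qualifying_taxa: int


@dataclass
class TaskSplit:
    """Train/validation/test assignment at one task size, per species."""

    size: int
    train: dict[str, list[str]]
    validation: dict[str, list[str]]
    test: dict[str, list[str]]


@dataclass
class RunManifest:
    """One experimental run: species window, seeds and nested task splits."""

    taxon: str
    run_index: int
    species: list[str]
    seed_species: int
    seed_split: int
    test: dict[str, list[str]]
    tasks: list[TaskSplit] = field(default_factory=list)


# ---------------------------------------------------------------------------
# eligibility

def eligible_species(observations: Iterable[ObservationRecord],
                     threshold: int = DEFAULT_THRESHOLD) -> dict[str, int]:
    """Species with at least ``threshold`` image-bearing observations.

    Returns species -> count of observations that carry >= 1 image; species
    below the threshold are omitted.  The boundary is inclusive.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts: dict[str, int] = {}
    for rec in observations:
        if rec.has_image:
            counts[rec.species] = counts.get(rec.species, 0) + 1
    return {sp: c for sp, c in counts.items() if c >= threshold}


def eligibility_report(observations: Sequence[ObservationRecord],
                       rank: str,
                       threshold: int = DEFAULT_THRESHOLD,
                       top_n: int | None = None) -> EligibilityReport:
    """Count eligible species per taxon at ``rank``.

    With ``top_n`` set, ``min_species`` is the minimum over the best
    ``top_n`` taxa (ranked by eligible-species count); otherwise over all
    taxa having at least one eligible species.
    """
    eligible = eligible_species(observations, threshold)
    taxon_of = {rec.species: rec.taxonomy.get(rank)
                for rec in observations if rec.species in eligible}
    taxa: dict[str, int] = {}
    for sp in eligible:
        taxon = taxon_of.get(sp)
        if taxon:
            taxa[taxon] = taxa.get(taxon, 0) + 1
    counts = sorted(taxa.values(), reverse=True)
    if top_n is not None:
        counts = counts[:top_n]
    return EligibilityReport(
        rank=rank,
        taxa=dict(sorted(taxa.items(), key=lambda kv: (-kv[1], kv[0]))),
        min_species=min(counts) if counts else 0,
        n_qualifying_taxa=len(taxa),
    )


def choose_taxon_level(observations: Sequence[ObservationRecord],
                       threshold: int = DEFAULT_THRESHOLD,
                       min_taxa: int = DEFAULT_MIN_TAXA,
                       ) -> tuple[str, EligibilityReport]:
    """Pick the grouping rank that maximizes the guaranteed species supply.

    Among ranks yielding at least ``min_taxa`` taxa with eligible species,
    the winner is the rank whose best ``min_taxa`` taxa have the largest
    minimum eligible-species count.  Ties go to the coarser rank.
    """
    best: tuple[str, EligibilityReport] | None = None
    for rank in GROUPING_RANKS:
        report = eligibility_report(observations, rank, threshold,
                                    top_n=min_taxa)
        if report.n_qualifying_taxa < min_taxa:
            continue
        if best is None or report.min_species > best[1].min_species:
            best = (rank, report)
    if best is None:
        raise ValueError(
            f"no rank yields >= {min_taxa} taxa with eligible species "
            f"at threshold {threshold}")
    return best


# ---------------------------------------------------------------------------
# species windows

def taxonomy_sort_key(taxonomy: Mapping[str, str]) -> str:
    """Case-insensitive sort key over the full kingdom..species path."""
    return "|".join(taxonomy.get(r, "") for r in RANKS).lower()


def select_species_window(taxonomy_by_species: Mapping[str, Mapping[str, str]],
                          window: int = DEFAULT_WINDOW,
                          seed: int = 0) -> list[str]:
    """Select ``window`` taxonomically consecutive species.

    Species are sorted by their full taxonomy path so that congeners and
    confamilials are adjacent; a uniformly random start index is drawn and
    the window wraps around the end of the list.  Deterministic given seed.
    """
    if len(taxonomy_by_species) < window:
        raise ValueError(
            f"need >= {window} eligible species, "
            f"got {len(taxonomy_by_species)}")
    ordered = sorted(taxonomy_by_species,
                     key=lambda sp: taxonomy_sort_key(
                         taxonomy_by_species[sp]))
    rng = np.random.default_rng(seed)
    start = int(rng.integers(len(ordered)))
    return [ordered[(start + i) % len(ordered)] for i in range(window)]


# ---------------------------------------------------------------------------
# splits and the reduction schedule

def reduction_schedule(start: int = DEFAULT_BASE,
                       stop_min: int = DEFAULT_STOP_MIN) -> list[int]:
    """Task sizes obtained by repeatedly discarding ``floor(n/4)``.

    The discard is exactly 25% when the size is divisible by 4 and slightly
    less otherwise; the sequence stops before any value below ``stop_min``.
    """
    if not start >= stop_min >= 1:
        raise ValueError("need start >= stop_min >= 1")
    sizes = [start]
    while True:
        nxt = sizes[-1] - sizes[-1] // 4
        if nxt < stop_min or nxt == sizes[-1]:
            break
        sizes.append(nxt)
    return sizes


def _split_base(obs_by_species: Mapping[str, Sequence[str]],
                base: int, rng: np.random.Generator) -> TaskSplit:
    val_n = base // 10
    train, validation, test = {}, {}, {}
    for sp in sorted(obs_by_species):
        ids = list(obs_by_species[sp])
        if len(ids) < base + MIN_TEST:
            raise ValueError(
                f"species {sp!r} has {len(ids)} observations, "
                f"needs >= {base + MIN_TEST}")
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        n_test = len(ids) - base
        test[sp] = sorted(shuffled[:n_test])
        kept = shuffled[n_test:]
        validation[sp] = sorted(kept[:val_n])
        train[sp] = sorted(kept[val_n:])
    return TaskSplit(size=base, train=train, validation=validation, test=test)


def assign_splits(obs_by_species: Mapping[str, Sequence[str]],
                  base: int = DEFAULT_BASE,
                  seed: int = 0) -> TaskSplit:
    """Assign the base task: per species, all but ``base`` observations go
    to the test set (at least 20), and the remaining ``base`` are split
    9:1 into training and validation.

    Assignment is at observation granularity, so all images of one
    observation land in the same subset.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    return _split_base(obs_by_species, base, rng)


def _reduce_task(task: TaskSplit, size: int,
                 rng: np.random.Generator) -> TaskSplit:
    """Draw the next, strictly smaller task as a nested uniform subset."""
    val_n = size // 10
    train_n = size - val_n
    train, validation = {}, {}
    for sp in sorted(task.train):
        keep_t = rng.choice(len(task.train[sp]), size=train_n, replace=False)
        keep_v = rng.choice(len(task.validation[sp]), size=val_n,
                            replace=False)
        train[sp] = sorted(task.train[sp][i] for i in keep_t)
        validation[sp] = sorted(task.validation[sp][i] for i in keep_v)
    return TaskSplit(size=size, train=train, validation=validation,
                     test=task.test)


def build_tasks(obs_by_species: Mapping[str, Sequence[str]],
                base: int = DEFAULT_BASE,
                stop_min: int = DEFAULT_STOP_MIN,
                seed: int = 0) -> list[TaskSplit]:
    """Base split plus the full nested reduction schedule, one rng stream."""
    rng = np.random.default_rng(seed)
    tasks = [_split_base(obs_by_species, base, rng)]
    for size in reduction_schedule(base, stop_min)[1:]:
        tasks.append(_reduce_task(tasks[-1], size, rng))
    return tasks


# ---------------------------------------------------------------------------
# run generation

def derive_seeds(master_seed: int, taxon: str, run_index: int,
                 ) -> tuple[int, int]:
    """Derive the (species-window, split) seed pair for one run.

    Uses a SeedSequence keyed on the master seed, a stable hash of the
    taxon name, and the run index; the resulting 32-bit integers are stored
    in the manifest so the run can be regenerated without the master seed.
    """
    taxon_key = sum(ord(c) * 31 ** (i % 7) for i, c in enumerate(taxon))
    ss = np.random.SeedSequence([master_seed, taxon_key % (2 ** 31),
                                 run_index])
    a, b = (int(x) for x in ss.generate_state(2))
    return a % (2 ** 31), b % (2 ** 31)


def _image_obs_by_species(observations: Iterable[ObservationRecord],
                          ) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for rec in observations:
        if rec.has_image:
            out.setdefault(rec.species, []).append(rec.observation_id)
    return out


def generate_run(observations: Sequence[ObservationRecord],
                 taxon: str,
                 run_index: int,
                 seed_species: int,
                 seed_split: int,
                 rank: str = "order",
                 threshold: int = DEFAULT_THRESHOLD,
                 window: int = DEFAULT_WINDOW,
                 base: int = DEFAULT_BASE,
                 stop_min: int = DEFAULT_STOP_MIN) -> RunManifest:
    """Generate a single run for one taxon from explicit seeds."""
    members = [rec for rec in observations
               if rec.taxonomy.get(rank) == taxon]
    eligible = eligible_species(members, threshold)
    taxonomy_by_species = {rec.species: rec.taxonomy for rec in members
                           if rec.species in eligible}
    species = select_species_window(taxonomy_by_species, window,
                                    seed_species)
    obs_by_species = _image_obs_by_species(members)
    selected = {sp: obs_by_species[sp] for sp in species}
    tasks = build_tasks(selected, base, stop_min, seed_split)
    return RunManifest(taxon=taxon, run_index=run_index,
                       species=species,
                       seed_species=seed_species, seed_split=seed_split,
                       test=tasks[0].test, tasks=tasks)


def generate_runs(observations: Sequence[ObservationRecord],
                  taxa: Sequence[str],
                  n_runs: int = DEFAULT_N_RUNS,
                  rank: str = "order",
                  threshold: int = DEFAULT_THRESHOLD,
                  window: int = DEFAULT_WINDOW,
                  base: int = DEFAULT_BASE,
                  stop_min: int = DEFAULT_STOP_MIN,
                  master_seed: int = 0) -> list[RunManifest]:
    """Generate ``n_runs`` runs for each taxon, seeds derived and recorded."""
    manifests = []
    for taxon in taxa:
        for run_index in range(1, n_runs + 1):
            seed_species, seed_split = derive_seeds(master_seed, taxon,
                                                    run_index)
            manifests.append(generate_run(
                observations, taxon, run_index, seed_species, seed_split,
                rank=rank, threshold=threshold, window=window, base=base,
                stop_min=stop_min))
    return manifests


def regenerate_run(observations: Sequence[ObservationRecord],
                   manifest: RunManifest,
                   rank: str = "order",
                   threshold: int = DEFAULT_THRESHOLD,
                   base: int = DEFAULT_BASE,
                   stop_min: int = DEFAULT_STOP_MIN) -> RunManifest:
    """Rebuild a run from the seeds stored in its manifest."""
    return generate_run(observations, manifest.taxon, manifest.run_index,
                        manifest.seed_species, manifest.seed_split,
                        rank=rank, threshold=threshold,
                        window=len(manifest.species), base=base,
                        stop_min=stop_min)


# ---------------------------------------------------------------------------
# audit

def summarize_observations(observations: Sequence[ObservationRecord],
                           ) -> dict:
    """Descriptive statistics: observations, images, images-per-observation."""
    img_counts = [len(rec.image_refs) for rec in observations]
    if not img_counts:
        return {"empty": True, "n_observations": 0, "n_images": 0,
                "images_per_obs_mean": 0.0, "images_per_obs_median": 0,
                "images_per_obs_max": 0}
    return {
        "empty": False,
        "n_observations": len(img_counts),
        "n_images": sum(img_counts),
        "images_per_obs_mean": sum(img_counts) / len(img_counts),
        "images_per_obs_median": statistics.median(img_counts),
        "images_per_obs_max": max(img_counts),
    }
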