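"""Synthetic citizen-science data with known ground truth.

Real citizen-science occurrence streams have a few statistical signatures
that matter to this pipeline: per-species observation counts are heavily
right-skewed (a few popular species dominate), most observations carry a
single image with a long right tail of multi-image records, and only a
minority of species clear any fixed data-availability threshold.  The
generator reproduces those signatures with configurable distributions and
keeps an exact ledger of every draw, so every downstream stage can be
verified against planted truth: eligibility filtering, bias statistics,
split protocols, and — via per-order Von Bertalanffy ground-truth
parameters — learning-curve recovery and VoI estimates.

Model performance itself is emulated two ways: ``generate_performance``
draws F1 values directly from the planted curves plus Gaussian noise (the
fast path used for fitting tests), while ``proxy_classifier_experiment``
actually trains and evaluates a nearest-centroid classifier on synthetic
feature vectors, producing qualitatively realistic rising learning curves
from a genuine train/evaluate loop over the manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dwc_io import (ChecklistEntry, ObservationRecord, write_checklist,
                     write_occurrences)
from .learning_curve import VBGFParams, vbgf, vbgf_slope
from .model_eval import RESULTS_COLUMNS
from .run_generation import RunManifest

LEDGER_SCHEMA_VERSION = 1


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic world; defaults mirror the study design.

    Twelve orders each carry enough eligible species (>= 220 image-bearing
    observations) for the 17-species windows; a few background orders fall
    below threshold so eligibility logic is exercised both ways, and the
    checklist lists species never observed so checklist richness exceeds
    observed richness.
    """

    n_orders: int = 12               # orders planted with eligible species
    species_per_order: int = 18      # eligible species per planted order
    sub_threshold_species: int = 4   # below-threshold species per order
    unobserved_species: int = 10     # checklist-only species per order
    n_background_orders: int = 3     # orders with no eligible species
    background_species: int = 8
    families_per_order: int = 4
    threshold: int = 220
    # extra image-bearing observations above threshold: discretized
    # log-normal, median ~e^mu
    obs_extra_mu: float = 3.0
    obs_extra_sigma: float = 0.8
    # image-bearing observations for sub-threshold/background species
    obs_low_mu: float = 3.5
    obs_low_sigma: float = 1.0
    imageless_fraction: float = 0.2  # binomial share of image-less records
    img_geom_p: float = 0.7          # images per image-bearing observation:
    img_max: int = 17                # truncated geometric on {1..img_max}
    vbgf_truth: dict[str, tuple[float, float, float]] | None = None
    noise_sigma: float = 0.02
    master_seed: int = 0

    def order_names(self) -> list[str]:
        return [f"Ordo{i + 1:02d}" for i in range(self.n_orders)]

    def background_order_names(self) -> list[str]:
        return [f"Rarordo{i + 1:02d}" for i in range(self.n_background_orders)]

    def truth(self) -> dict[str, VBGFParams]:
        """Planted per-order learning-curve parameters.

        Defaults spread L_inf over 0.70-0.95 and k over 0.012-0.040 so the
        orders have visibly distinct curves; t0 cycles over small negative
        values, as fitted curves on real data typically show.
        """
        if self.vbgf_truth is not None:
            return {o: VBGFParams(*p) for o, p in self.vbgf_truth.items()}
        names = self.order_names()
        n = max(len(names) - 1, 1)
        out = {}
        for i, name in enumerate(names):
            l_inf = 0.70 + 0.25 * i / n
            k = 0.012 + 0.028 * ((i * 5) % len(names)) / n
            t0 = -15.0 + 5.0 * (i % 4)
            out[name] = VBGFParams(l_inf, k, t0)
        return out


@dataclass
class GroundTruthLedger:
    """Exact record of what the generator emitted."""

    per_species: dict[str, dict] = field(default_factory=dict)
    per_order: dict[str, dict] = field(default_factory=dict)
    vbgf_truth: dict[str, tuple[float, float, float]] = field(
        default_factory=dict)
    noise_sigma: float = 0.0
    master_seed: int = 0

    def true_params(self, order: str) -> VBGFParams:
        return VBGFParams(*self.vbgf_truth[order])

    def true_f1(self, order: str, t: float) -> float:
        return float(vbgf(t, self.true_params(order)))

    def true_slope(self, order: str, t: float) -> float:
        return float(vbgf_slope(t, self.true_params(order)))

    def to_json(self, path: str | Path) -> None:
        payload = {"schema_version": LEDGER_SCHEMA_VERSION, **asdict(self)}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthLedger":
        payload = json.loads(Path(path).read_text())
        payload.pop("schema_version", None)
        payload["vbgf_truth"] = {o: tuple(p) for o, p
                                 in payload["vbgf_truth"].items()}
        return cls(**payload)


@dataclass
class SyntheticArchive:
    records: list[ObservationRecord]
    checklist: list[ChecklistEntry]
    ledger: GroundTruthLedger


def _discrete_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                        size: int) -> np.ndarray:
    return np.maximum(np.rint(rng.lognormal(mu, sigma, size)), 1).astype(int)


def _species_plan(config: SyntheticConfig, rng: np.random.Generator):
    """Plan (species, taxonomy, n image-bearing obs) for every species."""
    plan = []
    kingdom = "Animalia"
    all_orders = ([(o, True) for o in config.order_names()]
                  + [(o, False) for o in config.background_order_names()])
    for oi, (order, planted) in enumerate(all_orders):
        phylum = f"Phylum{oi % 3 + 1}"
        klass = f"Classis{oi % 4 + 1}"
        n_elig = config.species_per_order if planted else 0
        n_sub = (config.sub_threshold_species if planted
                 else config.background_species)
        extras = _discrete_lognormal(rng, config.obs_extra_mu,
                                     config.obs_extra_sigma, n_elig)
        lows = np.minimum(
            _discrete_lognormal(rng, config.obs_low_mu,
                                config.obs_low_sigma, n_sub),
            config.threshold - 1)
        counts = list(config.threshold + extras) + list(lows)
        for si, n_img_obs in enumerate(counts):
            family = f"{order}fam{si % config.families_per_order + 1}"
            genus = f"{order}gen{si // 2 + 1:02d}"
            species = f"{genus} species{si + 1:02d}"
            taxonomy = {"kingdom": kingdom, "phylum": phylum,
                        "class": klass, "order": order, "family": family,
                        "genus": genus, "species": species}
            plan.append((species, taxonomy, int(n_img_obs)))
    return plan


def generate_archive(config: SyntheticConfig | None = None,
                     ) -> SyntheticArchive:
    """Draw the full synthetic archive: records, checklist and ledger.

    Deterministic given ``config.master_seed``; the ledger is written from
    the same draw as the records, so the two agree exactly.
    """
    config = config or SyntheticConfig()
    if config.species_per_order and config.species_per_order < 1:
        raise ValueError("species_per_order must be >= 1")
    if not 0 <= config.imageless_fraction < 1:
        raise ValueError("imageless_fraction must be in [0, 1)")
    rng = np.random.default_rng(config.master_seed)
    plan = _species_plan(config, rng)

    records: list[ObservationRecord] = []
    ledger = GroundTruthLedger(
        vbgf_truth={o: (p.l_inf, p.k, p.t0)
                    for o, p in config.truth().items()},
        noise_sigma=config.noise_sigma,
        master_seed=config.master_seed)

    obs_counter = 0
    for species, taxonomy, n_img_obs in plan:
        order = taxonomy["order"]
        n_imageless = int(rng.binomial(n_img_obs, config.imageless_fraction))
        imgs_per_obs = np.minimum(
            rng.geometric(config.img_geom_p, n_img_obs), config.img_max)
        n_images = 0
        for j in range(n_img_obs + n_imageless):
            obs_counter += 1
            oid = f"obs{obs_counter:07d}"
            if j < n_img_obs:
                refs = tuple(f"{oid}img{m + 1}"
                             for m in range(int(imgs_per_obs[j])))
                n_images += len(refs)
            else:
                refs = ()
            records.append(ObservationRecord(
                observation_id=oid, species=species, taxonomy=taxonomy,
                image_refs=refs))
        ledger.per_species[species] = {
            "order": order,
            "n_obs": n_img_obs + n_imageless,
            "n_image_obs": n_img_obs,
            "n_images": n_images,
        }
        agg = ledger.per_order.setdefault(order, {
            "n_obs": 0, "n_image_obs": 0, "n_images": 0,
            "n_species_observed": 0, "n_species_checklist": 0,
            "n_eligible": 0})
        agg["n_obs"] += n_img_obs + n_imageless
        agg["n_image_obs"] += n_img_obs
        agg["n_images"] += n_images
        agg["n_species_observed"] += 1
        if n_img_obs >= config.threshold:
            agg["n_eligible"] += 1

    checklist = []
    for order in (config.order_names() + config.background_order_names()):
        agg = ledger.per_order[order]
        total = agg["n_species_observed"] + config.unobserved_species
        agg["n_species_checklist"] = total
        checklist.append(ChecklistEntry(order, "order", total))
    return SyntheticArchive(records=records, checklist=checklist,
                            ledger=ledger)


def write_archive(archive: SyntheticArchive, outdir: str | Path) -> dict:
    """Write occurrence/multimedia/checklist TSVs plus the ledger JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrence": outdir / "occurrence.tsv",
        "multimedia": outdir / "multimedia.tsv",
        "checklist": outdir / "checklist.tsv",
        "ledger": outdir / "ledger.json",
    }
    write_occurrences(archive.records, paths["occurrence"],
                      paths["multimedia"])
    write_checklist(archive.checklist, paths["checklist"])
    archive.ledger.to_json(paths["ledger"])
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# performance emulation

def generate_performance(config: SyntheticConfig,
                         manifests: Sequence[RunManifest],
                         seed: int | None = None,
                         as_confusion: bool = False) -> pd.DataFrame:
    """Emulate the per-task model scores the 660 trainings would produce.

    For each task of size t in each manifest an F1 is drawn as
    ``clip(L(t; truth) + N(0, noise_sigma), 0, 1)``.  With
    ``as_confusion`` the value is expanded into per-class integer counts
    (tp out of the class's test size, fn the remainder, fp mirrored) whose
    macro-F1 is within half a count of the drawn value.
    """
    truth = config.truth()
    rng = np.random.default_rng(config.master_seed + 1 if seed is None
                                else seed)
    f1_rows, conf_rows = [], []
    for m in manifests:
        params = truth[m.taxon]
        for task in m.tasks:
            f1 = float(np.clip(
                vbgf(task.size, params)
                + rng.normal(0.0, config.noise_sigma), 0.0, 1.0))
            f1_rows.append((m.taxon, m.run_index, task.size, f1))
            if as_confusion:
                for sp in m.species:
                    n_test = len(m.test[sp])
                    tp = int(round(f1 * n_test))
                    fn = n_test - tp
                    conf_rows.append((m.taxon, m.run_index, task.size, sp,
                                      tp, fn, fn))
    if as_confusion:
        return pd.DataFrame(conf_rows, columns=RESULTS_COLUMNS)
    return pd.DataFrame(f1_rows, columns=["taxon", "run", "size", "f1"])


def proxy_classifier_experiment(manifest: RunManifest,
                                separability: float = 1.5,
                                dim: int = 8,
                                seed: int = 0) -> pd.DataFrame:
    """Train/evaluate a nearest-centroid classifier over a run's tasks.

    Each species gets a latent class mean drawn from N(0, separability^2 I)
    in ``dim`` dimensions; each observation contributes one feature vector
    (mean + unit Gaussian noise).  Per task, class centroids are estimated
    from that task's training observations only and every test observation
    is assigned to the nearest centroid.  Larger training tasks estimate
    centroids better, so expected F1 rises with task size; larger
    separability raises the achievable asymptote.

    Returns a per-class confusion table in the layout ``collect_points``
    consumes.
    """
    rng = np.random.default_rng(seed)
    species = sorted(manifest.species)
    means = {sp: rng.normal(0.0, separability, dim) for sp in species}
    features: dict[str, np.ndarray] = {}
    for sp in species:
        base = manifest.tasks[0]
        ids = (base.train[sp] + base.validation[sp] + manifest.test[sp])
        for oid in sorted(ids):
            features[oid] = means[sp] + rng.normal(0.0, 1.0, dim)

    rows = []
    for task in manifest.tasks:
        centroids = np.stack([
            np.mean([features[oid] for oid in task.train[sp]], axis=0)
            for sp in species])
        counts = {sp: {"tp": 0, "fp": 0, "fn": 0} for sp in species}
        for sp in species:
            for oid in manifest.test[sp]:
                d = np.linalg.norm(centroids - features[oid], axis=1)
                pred = species[int(np.argmin(d))]
                if pred == sp:
                    counts[sp]["tp"] += 1
                else:
                    counts[sp]["fn"] += 1
                    counts[pred]["fp"] += 1
        for sp in species:
            rows.append((manifest.taxon, manifest.run_index, task.size, sp,
                         counts[sp]["tp"], counts[sp]["fp"],
                         counts[sp]["fn"]))
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)
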