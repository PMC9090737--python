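"""Eligibility, species windows, split protocol and reduction schedule."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxovoi import (ObservationRecord, assign_splits, choose_taxon_level,
                     eligible_species, generate_runs, reduction_schedule,
                     regenerate_run, select_species_window,
                     summarize_observations)
from taxovoi.run_generation import (GROUPING_RANKS, build_tasks,
                                    eligibility_report, taxonomy_sort_key)


def _species_records(species, n_with_images, n_without=0, order="Ordo01",
                     family="Fam1", genus=None):
    genus = genus or species.split()[0]
    taxonomy = {"kingdom": "Animalia", "phylum": "P", "class": "C",
                "order": order, "family": family, "genus": genus,
                "species": species}
    recs = []
    for i in range(n_with_images + n_without):
        oid = f"{species.replace(' ', '')}-{i:04d}"
        refs = (f"{oid}img",) if i < n_with_images else ()
        recs.append(ObservationRecord(oid, species, taxonomy, refs))
    return recs


class TestEligibility:
    def test_threshold_boundary_inclusive(self):
        records = (_species_records("Aa aa", 220)
                   + _species_records("Bb bb", 219))
        assert eligible_species(records) == {"Aa aa": 220}

    def test_imageless_observations_do_not_count(self):
        records = _species_records("Aa aa", 219, n_without=50)
        assert eligible_species(records) == {}

    def test_matches_generator_ledger(self, tiny_archive):
        threshold = 220
        expected = {sp: truth["n_image_obs"]
                    for sp, truth in tiny_archive.ledger.per_species.items()
                    if truth["n_image_obs"] >= threshold}
        assert eligible_species(tiny_archive.records, threshold) == expected


class TestChooseTaxonLevel:
    @staticmethod
    def _toy_records():
        """4 'orders' x 3 eligible species, but only genus has >= 4 taxa
        with one species each -- constructed so order wins at min_taxa=4."""
        recs = []
        for oi in range(4):
            for si in range(3):
                recs += _species_records(
                    f"Gen{oi}{si} sp", 10, order=f"Order{oi}",
                    family=f"Fam{oi}{si % 2}", genus=f"Gen{oi}{si}")
        return recs

    def test_rank_maximizing_minimum(self):
        rank, report = choose_taxon_level(self._toy_records(), threshold=5,
                                          min_taxa=4)
        # order: 4 taxa x 3 species (min 3); family: 8 taxa x 1-2 (min <3);
        # genus: 12 taxa x 1
        assert rank == "order"
        assert report.min_species == 3

    def test_only_qualifying_rank_wins(self):
        # single order, 12 genera: only genus reaches 12 distinct taxa
        recs = []
        for gi in range(12):
            recs += _species_records(f"Gen{gi:02d} sp", 10, order="Solo",
                                     genus=f"Gen{gi:02d}")
        rank, _ = choose_taxon_level(recs, threshold=5, min_taxa=12)
        assert rank == "genus"

    def test_no_qualifying_rank_raises(self):
        with pytest.raises(ValueError, match="no rank"):
            choose_taxon_level(_species_records("Aa aa", 300), threshold=5,
                               min_taxa=12)

    def test_agrees_with_bruteforce_oracle(self, tiny_archive):
        min_taxa, threshold = 2, 220
        eligible = eligible_species(tiny_archive.records, threshold)
        taxonomy = {r.species: r.taxonomy for r in tiny_archive.records}
        best_rank, best_min = None, -1
        for rank in GROUPING_RANKS:
            counts = {}
            for sp in eligible:
                taxon = taxonomy[sp].get(rank)
                if taxon:
                    counts[taxon] = counts.get(taxon, 0) + 1
            if len(counts) < min_taxa:
                continue
            top = sorted(counts.values(), reverse=True)[:min_taxa]
            if min(top) > best_min:
                best_rank, best_min = rank, min(top)
        rank, report = choose_taxon_level(tiny_archive.records, threshold,
                                          min_taxa)
        assert (rank, report.min_species) == (best_rank, best_min)

    def test_planted_synthetic_dataset_selects_order(self, default_archive):
        rank, report = choose_taxon_level(default_archive.records)
        assert rank == "order"
        assert report.n_qualifying_taxa == 12
        assert report.min_species >= 17


class TestSpeciesWindow:
    @staticmethod
    def _taxonomies(n, order="Ordo01"):
        return {f"Gen{i:02d} sp": {"kingdom": "K", "phylum": "P",
                                   "class": "C", "order": order,
                                   "family": f"Fam{i // 5}",
                                   "genus": f"Gen{i:02d}",
                                   "species": f"Gen{i:02d} sp"}
                for i in range(n)}

    def test_exact_window_returns_all_in_taxonomy_order(self):
        tax = self._taxonomies(17)
        window = select_species_window(tax, window=17, seed=99)
        assert sorted(window) == sorted(tax)

    def test_wraparound(self):
        tax = self._taxonomies(20)
        ordered = sorted(tax, key=lambda sp: taxonomy_sort_key(tax[sp]))
        # find a seed that starts at index 17 to exercise the wrap
        for seed in range(500):
            window = select_species_window(tax, window=17, seed=seed)
            if window[0] == ordered[17]:
                assert window == ordered[17:] + ordered[:14]
                return
        pytest.fail("no seed produced start index 17")

    def test_deterministic_and_start_coverage(self):
        tax = self._taxonomies(20)
        ordered = sorted(tax, key=lambda sp: taxonomy_sort_key(tax[sp]))
        starts = set()
        for seed in range(300):
            w1 = select_species_window(tax, 17, seed)
            assert w1 == select_species_window(tax, 17, seed)
            starts.add(ordered.index(w1[0]))
        assert starts == set(range(20))

    def test_too_few_species_raises(self):
        with pytest.raises(ValueError, match="eligible species"):
            select_species_window(self._taxonomies(16), 17, 0)

    def test_congeners_contiguous_in_sort(self):
        tax = {sp: t for sp, t in self._taxonomies(30).items()}
        ordered = sorted(tax, key=lambda sp: taxonomy_sort_key(tax[sp]))
        genera = [tax[sp]["genus"] for sp in ordered]
        seen = set()
        for i, g in enumerate(genera):
            if g in seen and genera[i - 1] != g:
                pytest.fail(f"genus {g} not contiguous")
            seen.add(g)


class TestAssignSplits:
    def test_exact_220_gives_20_180_20(self):
        ids = {"Aa aa": [f"o{i}" for i in range(220)]}
        task = assign_splits(ids, base=200, seed=3)
        assert len(task.test["Aa aa"]) == 20
        assert len(task.train["Aa aa"]) == 180
        assert len(task.validation["Aa aa"]) == 20

    def test_300_observations_gives_100_test(self):
        ids = {"Aa aa": [f"o{i}" for i in range(300)]}
        task = assign_splits(ids, base=200, seed=3)
        assert len(task.test["Aa aa"]) == 100

    def test_partition_and_disjointness(self):
        ids = {"Aa aa": [f"o{i}" for i in range(260)]}
        task = assign_splits(ids, seed=5)
        parts = [set(task.train["Aa aa"]), set(task.validation["Aa aa"]),
                 set(task.test["Aa aa"])]
        assert sum(len(p) for p in parts) == 260
        assert set.union(*parts) == set(ids["Aa aa"])

    def test_below_minimum_names_species(self):
        with pytest.raises(ValueError, match="Aa aa"):
            assign_splits({"Aa aa": [f"o{i}" for i in range(219)]})

    def test_deterministic(self):
        ids = {"Aa aa": [f"o{i}" for i in range(240)],
               "Bb bb": [f"p{i}" for i in range(230)]}
        assert assign_splits(ids, seed=42) == assign_splits(ids, seed=42)


class TestReductionSchedule:
    def test_printed_sequence(self):
        assert reduction_schedule(200, 10) == [200, 150, 113, 85, 64, 48,
                                               36, 27, 21, 16, 12]

    def test_start_at_stop_min(self):
        assert reduction_schedule(10, 10) == [10]

    @given(st.integers(10, 5000))
    @settings(max_examples=200, derandomize=True)
    def test_discard_rule_and_ratio_bounds(self, start):
        sched = reduction_schedule(start, 10)
        assert sched[0] == start
        for a, b in zip(sched, sched[1:]):
            assert b == a - a // 4
            assert 0.75 <= b / a <= 0.8
        assert all(s >= 10 for s in sched)
        nxt = sched[-1] - sched[-1] // 4
        assert nxt < 10 or nxt == sched[-1]


@pytest.fixture(scope="module")
def tasks():
    ids = {f"Sp{j} x": [f"s{j}o{i}" for i in range(230 + 10 * j)]
           for j in range(3)}
    return build_tasks(ids, seed=8)


class TestTaskNesting:
    def test_sizes_follow_schedule(self, tasks):
        assert [t.size for t in tasks] == reduction_schedule(200, 10)

    def test_train_val_counts_and_validation_fraction(self, tasks):
        for task in tasks:
            for sp in task.train:
                n_val = len(task.validation[sp])
                assert n_val == task.size // 10
                assert len(task.train[sp]) + n_val == task.size
                assert n_val / task.size <= 0.10

    def test_nested_subsets(self, tasks):
        for prev, nxt in zip(tasks, tasks[1:]):
            for sp in prev.train:
                prev_pool = set(prev.train[sp]) | set(prev.validation[sp])
                next_pool = set(nxt.train[sp]) | set(nxt.validation[sp])
                assert next_pool < prev_pool

    def test_test_set_constant_and_disjoint(self, tasks):
        for task in tasks:
            assert task.test is tasks[0].test
            for sp in task.train:
                pool = set(task.train[sp]) | set(task.validation[sp])
                assert not pool & set(task.test[sp])
                assert not set(task.train[sp]) & set(task.validation[sp])


class TestGenerateRuns:
    def test_design_combinatorics(self, tiny_archive):
        orders = sorted(o for o, d in tiny_archive.ledger.per_order.items()
                        if d["n_eligible"] >= 17)
        manifests = generate_runs(tiny_archive.records, orders, n_runs=2,
                                  master_seed=4)
        assert len(manifests) == 2 * len(orders)
        assert all(len(m.tasks) == 11 for m in manifests)
        assert all(len(m.species) == 17 for m in manifests)
        assert all(m.tasks[0].size == 200 for m in manifests)

    def test_regeneration_from_stored_seeds(self, tiny_archive):
        orders = sorted(o for o, d in tiny_archive.ledger.per_order.items()
                        if d["n_eligible"] >= 17)
        manifest = generate_runs(tiny_archive.records, orders[:1],
                                 n_runs=1, master_seed=123)[0]
        assert regenerate_run(tiny_archive.records, manifest) == manifest

    def test_distinct_seeds_across_runs(self, tiny_archive):
        orders = sorted(o for o, d in tiny_archive.ledger.per_order.items()
                        if d["n_eligible"] >= 17)
        manifests = generate_runs(tiny_archive.records, orders, n_runs=3,
                                  master_seed=0)
        seeds = {(m.seed_species, m.seed_split) for m in manifests}
        assert len(seeds) == len(manifests)


class TestSummarize:
    def test_hand_example(self):
        recs = (_species_records("Aa aa", 1)  # 1 image
                + [ObservationRecord("x1", "Bb bb",
                                     {"kingdom": "K", "class": "C",
                                      "order": "O", "species": "Bb bb"},
                                     ("a", "b", "c"))])
        s = summarize_observations(recs)
        assert (s["images_per_obs_mean"], s["images_per_obs_median"],
                s["images_per_obs_max"]) == (2.0, 2, 3)

    def test_empty(self):
        s = summarize_observations([])
        assert s["empty"] and s["n_observations"] == 0

    def test_matches_ledger(self, tiny_archive):
        s = summarize_observations(tiny_archive.records)
        ledger = tiny_archive.ledger
        assert s["n_observations"] == sum(d["n_obs"] for d
                                          in ledger.per_order.values())
        assert s["n_images"] == sum(d["n_images"] for d
                                    in ledger.per_order.values())
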