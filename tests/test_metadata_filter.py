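"""Entry-level filter semantics: predicates, reasons, and set-level invariants."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rnacurate.catalog import Catalog, EntryMeta
from rnacurate.metadata_filter import ConfigError, MetadataFilterConfig, filter_metadata

from test_catalog import make_entry


def run(entries, **cfg):
    catalog = Catalog(entries=tuple(entries))
    return filter_metadata(catalog, MetadataFilterConfig(**cfg))


class TestPredicates:
    def test_xray_below_resolution_with_keyword_retained(self):
        entry = make_entry(resolution=3.5, keywords="RNA")
        kept, removed = run([entry], methods={"X-RAY DIFFRACTION"},
                            max_resolution=3.6, include_keywords={"RNA"})
        assert kept.ids() == ["1ABC"] and removed == []

    def test_missing_resolution_fails_strict_policy(self):
        entry = make_entry(experimental_method="SOLUTION NMR", resolution=None)
        kept, removed = run([entry], max_resolution=3.6)
        assert removed == [("1ABC", "resolution")]

    def test_missing_resolution_passes_when_allowed(self):
        entry = make_entry(experimental_method="SOLUTION NMR", resolution=None)
        kept, _ = run([entry], max_resolution=3.6, allow_missing_resolution=True)
        assert kept.ids() == ["1ABC"]

    def test_year_before_is_exclusive(self):
        e2023 = make_entry("1AAA", release_year=2023)
        e2022 = make_entry("2BBB", release_year=2022)
        kept, removed = run([e2023, e2022], year_before=2023)
        assert kept.ids() == ["2BBB"]
        assert removed == [("1AAA", "year")]

    def test_year_range_is_inclusive(self):
        entries = [make_entry(f"{i}AAA", release_year=y)
                   for i, y in [(1, 2019), (2, 2020), (3, 2022), (4, 2023)]]
        kept, _ = run(entries, year_range=(2020, 2022))
        assert kept.ids() == ["2AAA", "3AAA"]

    def test_entity_type_containment_and_exclusion(self):
        rna_only = make_entry("1AAA", polymer_entity_types={"RNA"})
        complex_ = make_entry("2BBB", polymer_entity_types={"RNA", "protein"})
        kept, _ = run([rna_only, complex_], required_entity_types={"RNA"},
                      forbidden_entity_types={"protein"})
        assert kept.ids() == ["1AAA"]

    def test_keyword_match_is_case_insensitive_substring(self):
        entry = make_entry(keywords="Transfer RNA / Ligase complex")
        kept, _ = run([entry], include_keywords={"transfer rna"})
        assert kept.ids() == ["1ABC"]
        _, removed = run([entry], exclude_keywords={"LIGASE"})
        assert removed == [("1ABC", "keywords")]

    def test_rna_subtype_intersection(self):
        entry = make_entry(rna_subtypes={"ncRNA"})
        kept, _ = run([entry], rna_subtypes={"ncrna", "rRNA"})
        assert kept.ids() == ["1ABC"]
        _, removed = run([entry], rna_subtypes={"rRNA"})
        assert removed == [("1ABC", "rna_subtypes")]

    def test_empty_config_is_identity(self):
        entries = [make_entry("1AAA"), make_entry("2BBB", resolution=None)]
        kept, removed = run(entries)
        assert kept.ids() == ["1AAA", "2BBB"] and removed == []

    def test_first_failing_predicate_is_the_reason(self):
        entry = make_entry(experimental_method="SOLUTION NMR", resolution=None,
                           keywords="DNA")
        _, removed = run([entry], methods={"X-RAY DIFFRACTION"}, max_resolution=3.6,
                         include_keywords={"RNA"})
        assert removed == [("1ABC", "method")]


class TestConfigValidation:
    def test_year_modes_mutually_exclusive(self):
        with pytest.raises(ConfigError):
            MetadataFilterConfig(year_before=2020, year_range=(2000, 2010))

    def test_nonpositive_resolution_rejected(self):
        with pytest.raises(ConfigError):
            MetadataFilterConfig(max_resolution=0.0)


def _entry_strategy():
    return st.builds(
        lambda i, method, res, year, kw: EntryMeta(
            pdb_id=f"{(i % 9) + 1}Q{i:02d}"[:4],
            experimental_method=method,
            resolution=res,
            release_year=year,
            keywords=kw,
            polymer_entity_types=frozenset({"RNA"}),
        ),
        st.integers(0, 98),
        st.sampled_from(["X-RAY DIFFRACTION", "SOLUTION NMR", "ELECTRON MICROSCOPY"]),
        st.one_of(st.none(), st.floats(0.8, 6.0, allow_nan=False)),
        st.integers(1990, 2026),
        st.sampled_from(["RNA", "DNA", "ribosome", "transfer RNA"]),
    )


_catalog_strategy = st.lists(_entry_strategy(), max_size=12).map(
    lambda es: Catalog(entries=tuple({e.pdb_id: e for e in es}.values()))
)

_config_strategy = st.builds(
    MetadataFilterConfig,
    methods=st.one_of(st.none(), st.just(frozenset({"X-RAY DIFFRACTION"}))),
    max_resolution=st.one_of(st.none(), st.floats(1.0, 5.0, allow_nan=False)),
    year_before=st.one_of(st.none(), st.integers(2000, 2026)),
    include_keywords=st.one_of(st.none(), st.just(frozenset({"RNA"}))),
    allow_missing_resolution=st.booleans(),
)


class TestInvariants:
    @given(_catalog_strategy, _config_strategy)
    def test_conservation_and_idempotence(self, catalog, config):
        kept, removed = filter_metadata(catalog, config)
        assert len(kept) + len(removed) == len(catalog)
        assert set(kept.ids()) | {pid for pid, _ in removed} == set(catalog.ids())
        again, removed_again = filter_metadata(kept, config)
        assert again.ids() == kept.ids() and removed_again == []

    @given(_catalog_strategy, _config_strategy)
    def test_adding_a_predicate_never_increases_survivors(self, catalog, config):
        kept, _ = filter_metadata(catalog, config)
        stricter = MetadataFilterConfig(
            methods=config.methods,
            max_resolution=config.max_resolution,
            year_before=config.year_before,
            include_keywords=config.include_keywords,
            allow_missing_resolution=config.allow_missing_resolution,
            rna_subtypes=frozenset({"ncRNA"}),
        )
        kept_stricter, _ = filter_metadata(catalog, stricter)
        assert len(kept_stricter) <= len(kept)

    @given(_catalog_strategy, _config_strategy, st.randoms(use_true_random=False))
    def test_survivor_set_invariant_under_permutation(self, catalog, config, rnd):
        entries = list(catalog.entries)
        rnd.shuffle(entries)
        permuted = Catalog(entries=tuple(entries))
        kept_a, _ = filter_metadata(catalog, config)
        kept_b, _ = filter_metadata(permuted, config)
        assert set(kept_a.ids()) == set(kept_b.ids())
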