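"""Name grammar, semantic checking, creation and reuse semantics."""

import copy

import pytest
from hypothesis import given, settings, strategies as st

from measurement_recorder.character_model import (
    MethodDefinition,
    clone_and_enhance,
    create_character,
    deprecate_character,
    parse_character_name,
    register_new_terms,
    render_character,
    semantic_check,
    use_this,
)
from measurement_recorder.errors import (
    DuplicateNameError,
    GrammarError,
    UnknownTermsError,
    ValidationError,
)
from measurement_recorder.ontology_store import equivalence_class, find_terms

from conftest import build_random_store


class TestNameGrammar:
    @pytest.mark.parametrize(
        "text, quality, preposition, structures",
        [
            ("length of leaf", "length", "of", ("leaf",)),
            ("distance between pupils", "distance", "between", ("pupils",)),
            ("Width  of  Perigynium Beak", "width", "of", ("perigynium beak",)),
            ("distance between apex and base", "distance", "between",
             ("apex", "base")),
        ],
    )
    def test_accepted_forms(self, text, quality, preposition, structures):
        name = parse_character_name(text)
        assert (name.quality, name.preposition, name.structures) == (
            quality, preposition, structures,
        )

    @pytest.mark.parametrize(
        "text",
        ["leaf length", "", "of leaf", "length of", "distance between apex",
         "distance between and", "between pupils"],
    )
    def test_rejected_forms(self, text):
        with pytest.raises(GrammarError):
            parse_character_name(text)

    @pytest.mark.parametrize(
        "text",
        ["length of leaf", "distance between pupils",
         "width of perigynium beak", "distance between apex and base",
         "length of tip of leaf"],
    )
    def test_parse_render_parse_is_fixed_point(self, text):
        once = parse_character_name(text)
        assert parse_character_name(once.text()) == once

    @settings(derandomize=True, max_examples=200)
    @given(
        quality=st.sampled_from(["length", "width", "distance", "angle"]),
        structure=st.lists(
            st.sampled_from(["leaf", "beak", "wing", "scale", "culm"]),
            min_size=1, max_size=3,
        ),
    )
    def test_fixed_point_on_generated_of_names(self, quality, structure):
        text = f"{quality} of {' '.join(structure)}"
        once = parse_character_name(text)
        assert once.text() == text
        assert parse_character_name(once.text()) == once


class TestSemanticCheck:
    def test_all_words_known(self, store):
        method = MethodDefinition(
            from_landmark="insertion of lowest scale",
            to_landmark="apex of inflorescence",
        )
        assert semantic_check(method, store).all_known

    def test_new_words_flagged_and_stopwords_ignored(self, store):
        # only "perigynium" is a term here; "of" is a stopword
        method = MethodDefinition(from_landmark="end of perigynium wings")
        report = semantic_check(method, store)
        assert report.new_words() == {"end", "wings"}
        statuses = dict(report.fields["from_landmark"])
        assert statuses["of"] == "stopword"
        assert statuses["perigynium"] == "known"

    def test_empty_method_is_all_known(self, store):
        assert semantic_check(MethodDefinition(), store).all_known

    def test_numbers_are_ignorable(self, store):
        report = semantic_check(MethodDefinition(at="2 to 3 beak"), store)
        assert report.new_words() == set()

    def test_deprecated_term_counts_as_new(self, store):
        from measurement_recorder.ontology_store import deprecate_term

        deprecate_term(find_terms("beak", store)[0].id, store)
        report = semantic_check(MethodDefinition(at="beak"), store)
        assert report.new_words() == {"beak"}


class TestRegisterNewTerms:
    def test_registration_makes_recheck_all_known(self, store):
        method = MethodDefinition(from_landmark="end of perigynium wings")
        report = semantic_check(method, store)
        created = register_new_terms(
            report,
            {"end": ("the extremity", "", ""), "wings": ("lateral flanges", "", "")},
            "tester",
            store,
        )
        assert {t.label for t in created} == {"end", "wings"}
        assert semantic_check(method, store).all_known

    def test_empty_report_is_noop(self, store):
        report = semantic_check(MethodDefinition(), store)
        assert register_new_terms(report, {}, "tester", store) == []

    def test_extra_or_missing_definitions_rejected(self, store):
        report = semantic_check(
            MethodDefinition(from_landmark="end of perigynium wings"), store
        )
        with pytest.raises(ValidationError, match="missing"):
            register_new_terms(report, {"end": ("", "", "")}, "t", store)
        with pytest.raises(ValidationError, match="not in the report"):
            register_new_terms(
                report,
                {"end": ("", "", ""), "wings": ("", "", ""), "spare": ("", "", "")},
                "t",
                store,
            )


class TestCreateCharacter:
    def test_valid_character_saved_with_usage_one(self, store):
        character = create_character(
            "length of leaf",
            MethodDefinition(from_landmark="base of leaf", to_landmark="tip of leaf"),
            "mm", "tester", store,
        )
        assert character.usage_count == 1
        assert character.history[0].kind == "created"
        assert character.id in store.characters
        leaf_id = find_terms("leaf", store)[0].id
        assert leaf_id in character.structure_terms

    def test_missing_unit_refused(self, store):
        with pytest.raises(ValidationError, match="unit"):
            create_character(
                "length of leaf", MethodDefinition(at="tip of leaf"),
                "", "tester", store,
            )

    def test_unknown_method_words_refused_with_report(self, store):
        with pytest.raises(UnknownTermsError) as exc:
            create_character(
                "length of leaf", MethodDefinition(at="flange of leaf"),
                "mm", "tester", store,
            )
        assert exc.value.report.new_words() == {"flange"}

    def test_duplicate_name_suggests_reuse_unless_forced(self, store):
        method = MethodDefinition(at="tip of leaf")
        create_character("length of leaf", method, "mm", "alice", store)
        with pytest.raises(DuplicateNameError) as exc:
            create_character("length of leaf", method, "mm", "bob", store)
        (hit,) = exc.value.suggestions
        assert hit.creators == ("alice",)
        assert hit.usage_count == 1
        forced = create_character(
            "length of leaf", method, "mm", "bob", store, force=True
        )
        assert forced.id != hit.character_id

    def test_method_or_illustration_required(self, store):
        with pytest.raises(ValidationError, match="landmark"):
            create_character(
                "length of leaf", MethodDefinition(), "mm", "t", store
            )
        ok = create_character(
            "length of leaf", MethodDefinition(), "mm", "t", store,
            illustrations=["leaf.png"],
        )
        assert ok.illustrations == ["leaf.png"]


class TestUseThis:
    def test_single_use_increments_by_one(self, shared_store):
        preloaded = max(
            shared_store.characters.values(), key=lambda c: c.usage_count
        )
        assert preloaded.usage_count == 20
        use_this(preloaded.id, "es01", shared_store)
        assert preloaded.usage_count == 21

    def test_n_uses_add_n(self, store):
        character = create_character(
            "length of leaf", MethodDefinition(at="tip of leaf"),
            "mm", "t", store,
        )
        for _ in range(5):
            use_this(character.id, "t", store)
        assert character.usage_count == 6

    def test_definition_untouched_by_use(self, store):
        character = create_character(
            "length of leaf", MethodDefinition(at="tip of leaf"),
            "mm", "alice", store,
        )
        before = copy.deepcopy(character.method)
        use_this(character.id, "bob", store)
        assert character.method == before
        assert character.unit == "mm"
        assert character.creators == ["alice"]

    def test_deprecated_character_refused(self, store):
        character = create_character(
            "length of leaf", MethodDefinition(at="tip of leaf"),
            "mm", "t", store,
        )
        deprecate_character(character.id, store)
        with pytest.raises(ValidationError):
            use_this(character.id, "t", store)


class TestCloneAndEnhance:
    def _source(self, store):
        return create_character(
            "length of inflorescence",
            MethodDefinition(
                from_landmark="insertion of lowest scale",
                to_landmark="apex of inflorescence",
            ),
            "mm", "Bruce Ford", store,
        )

    def test_shared_creatorship_and_equivalence(self, store):
        source = self._source(store)
        clone = clone_and_enhance(
            source.id,
            MethodDefinition(
                from_landmark="insertion of lowest scale",
                to_landmark="apex of inflorescence",
                exclude=["beak"],
            ),
            "es03", store,
        )
        assert clone.creators == ["Bruce Ford", "es03"]
        assert equivalence_class(source.id, store) == {source.id, clone.id}
        assert clone.usage_count == 1

    def test_identity_method_clone_is_still_new_and_equivalent(self, store):
        source = self._source(store)
        clone = clone_and_enhance(source.id, source.method, "es03", store)
        assert clone.id != source.id
        assert clone.id in equivalence_class(source.id, store)

    def test_clone_of_clone_gives_three_member_class(self, store):
        source = self._source(store)
        first = clone_and_enhance(source.id, source.method, "es03", store)
        second = clone_and_enhance(first.id, first.method, "es05", store)
        assert equivalence_class(source.id, store) == {
            source.id, first.id, second.id,
        }
        assert second.creators == ["Bruce Ford", "es03", "es05"]

    def test_source_untouched_except_cross_reference(self, store):
        source = self._source(store)
        method_before = copy.deepcopy(source.method)
        usage_before = source.usage_count
        clone = clone_and_enhance(
            source.id,
            MethodDefinition(from_landmark="apex of inflorescence"),
            "es03", store, unit="cm",
        )
        assert source.method == method_before
        assert source.unit == "mm"
        assert source.usage_count == usage_before
        assert source.history[-1].kind == "cloned_from"
        assert source.history[-1].payload == {"clone": clone.id}
        assert clone.unit == "cm"


class TestRender:
    def test_render_shows_method_unit_creators_usage(self, shared_store):
        task2 = next(
            c for c in shared_store.characters.values() if c.usage_count == 20
        )
        record = render_character(task2.id, shared_store)
        assert record["name"] == "length of inflorescence"
        assert "insertion of lowest scale" in record["method_text"]
        assert "apex of inflorescence" in record["method_text"]
        assert record["unit"] == "mm"
        assert record["creators"] == ["Bruce Ford"]
        assert record["usage_count"] == 20

    def test_render_after_use_shows_incremented_count(self, store):
        character = create_character(
            "length of leaf", MethodDefinition(at="tip of leaf"),
            "mm", "t", store,
        )
        use_this(character.id, "t", store)
        assert render_character(character.id, store)["usage_count"] == 2

    def test_character_without_illustrations_renders_empty_list(self, store):
        character = create_character(
            "length of leaf", MethodDefinition(at="tip of leaf"),
            "mm", "t", store,
        )
        assert render_character(character.id, store)["illustrations"] == []


class TestUsageInvariant:
    @pytest.mark.parametrize("seed", range(6))
    def test_usage_count_is_one_plus_used_events(self, seed):
        s = build_random_store(seed, n_ops=60)
        assert s.characters, "random sequence produced no characters"
        for character in s.characters.values():
            assert character.usage_count == 1 + character.used_events()
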