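import pytest

from chemlink.errors import UnknownClassError
from chemlink.fixtures import FixtureSpec, build_store
from chemlink.inference import (
    associate_side_effect_pathways,
    count_multiply_inhibited_pathways,
    find_pathway_inhibitors,
    find_polypharmacology,
    infer_compound_pathway,
)

from .oracles import polypharmacology_join_oracle


def hits_as_dicts(hits):
    return [
        {
            "cid": h.compound_id,
            "shared_targets": sorted(h.shared_targets),
            "path_count": h.path_count,
            "druglike": h.druglike,
        }
        for h in hits
    ]


def test_polypharmacology_recovers_planted_hits(store, manifest):
    hits = find_polypharmacology(store, manifest.drug_id)
    assert hits_as_dicts(hits) == manifest.polypharmacology_hits


def test_polypharmacology_decoys_each_fail_one_filter(store, manifest):
    """Without the drug-likeness gate, exactly the non-drug-like decoy joins
    the hit list; the score/outcome/single-target decoys never appear."""
    hits = find_polypharmacology(store, manifest.drug_id, require_druglike=False)
    assert hits_as_dicts(hits) == manifest.polypharmacology_hits_with_nondruglike


def test_polypharmacology_unknown_drug_raises(store):
    with pytest.raises(UnknownClassError):
        find_polypharmacology(store, "DB99999X")


def test_polypharmacology_min_shared_monotone(store, manifest):
    sizes = [
        len(find_polypharmacology(store, manifest.drug_id, min_shared=k))
        for k in (1, 2, 3, 4)
    ]
    assert sizes == sorted(sizes, reverse=True)
    assert sizes[3] == 0  # the drug only has 3 targets


def test_polypharmacology_matches_join_oracle(store, manifest, schema):
    for druglike in (True, False):
        hits = find_polypharmacology(
            store, manifest.drug_id, require_druglike=druglike, schema=schema
        )
        oracle = polypharmacology_join_oracle(
            store, schema, manifest.drug_id, require_druglike=druglike
        )
        assert [
            (h.compound_id, h.shared_targets, h.path_count, h.druglike) for h in hits
        ] == oracle


def test_compound_pathway_chain_cardinality(store, manifest):
    """A protein in two pathways yields one chain per (active record, pathway)."""
    chains = infer_compound_pathway(store)
    hit = manifest.pathway_inhibitor_hits[0]
    planted = [c for c in chains if c.compound_id == hit["cid"]]
    assert sorted({c.target_accession for c in planted}) == hit["targets"]
    assert all(c.pathway_id == hit["pathway_id"] for c in planted)
    assert len(chains) >= 2


def test_pathway_inhibitors_recover_planted_hit(store, manifest):
    hits = find_pathway_inhibitors(store, manifest.pathway_filter)
    assert [
        {"cid": h.compound_id, "pathway_id": h.pathway_id,
         "targets": sorted(h.inhibited_targets)}
        for h in hits
    ] == manifest.pathway_inhibitor_hits


def test_pathway_filter_is_case_insensitive_substring(store, manifest):
    lower = find_pathway_inhibitors(store, manifest.pathway_filter.lower())
    assert [h.compound_id for h in lower] == [
        h["cid"] for h in manifest.pathway_inhibitor_hits
    ]
    assert find_pathway_inhibitors(store, "no-such-pathway-name") == []


def test_duplicate_assays_on_one_target_do_not_count_twice(store, manifest):
    """Distinct targets gate the hit: two assays on a single protein stay out."""
    hits = find_pathway_inhibitors(store, manifest.pathway_filter, min_targets=2)
    assert all(len(h.inhibited_targets) >= 2 for h in hits)


def test_multiply_inhibited_pathway_count(store, manifest):
    count, detail = count_multiply_inhibited_pathways(store)
    assert count == len(manifest.multiply_inhibited_pathway_ids)
    assert sorted(detail) == sorted(manifest.multiply_inhibited_pathway_ids)


def test_multiply_inhibited_min_targets_one_counts_any_active_chain(store):
    count1, detail1 = count_multiply_inhibited_pathways(store, min_targets=1)
    count2, _ = count_multiply_inhibited_pathways(store, min_targets=2)
    assert count1 >= count2
    chains = infer_compound_pathway(store)
    assert count1 == len({c.pathway_id for c in chains})


def test_side_effect_association_recovers_planted_pathway(store, manifest):
    assocs = associate_side_effect_pathways(store, list(manifest.side_effect_terms))
    assert [
        {"pathway_id": a.pathway_id, "efficient_genes": sorted(a.efficient_genes),
         "path_count": a.associative_path_count}
        for a in assocs
    ] == manifest.side_effect_associations
    assert assocs[0].side_effect_terms == frozenset(manifest.side_effect_terms)


def test_side_effect_term_match_is_exact_but_case_insensitive(store, manifest):
    upper = [t.upper() for t in manifest.side_effect_terms]
    assert associate_side_effect_pathways(store, upper)
    # a prefix of the term is not a match (exact term equality, not substring)
    prefix = [t[:4] for t in manifest.side_effect_terms]
    assert associate_side_effect_pathways(store, prefix) == []


def test_side_effect_thresholds_are_monotone(store, manifest):
    terms = list(manifest.side_effect_terms)
    base = associate_side_effect_pathways(store, terms)
    stricter_drugs = associate_side_effect_pathways(store, terms, min_drugs_per_gene=3)
    stricter_genes = associate_side_effect_pathways(store, terms, min_genes_per_pathway=3)
    assert len(stricter_drugs) <= len(base)
    assert len(stricter_genes) <= len(base)


def test_planted_recovery_across_seeds():
    """The manifest stays exactly recoverable as the seed varies."""
    for seed in (11, 29):
        store, manifest = build_store(FixtureSpec(seed=seed))
        assert hits_as_dicts(find_polypharmacology(store, manifest.drug_id)) == \
            manifest.polypharmacology_hits
        hits = find_pathway_inhibitors(store, manifest.pathway_filter)
        assert [h.compound_id for h in hits] == [
            h["cid"] for h in manifest.pathway_inhibitor_hits
        ]
        assocs = associate_side_effect_pathways(store, list(manifest.side_effect_terms))
        assert [a.pathway_id for a in assocs] == [
            a["pathway_id"] for a in manifest.side_effect_associations
        ]
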