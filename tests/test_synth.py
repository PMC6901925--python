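import dataclasses
import json

import numpy as np
import pytest
from scipy import stats

from xkmir.align import permutation_pvalue, smith_waterman
from xkmir.coexnet import mi_from_rho
from xkmir.netmodules import hypergeom_right_tail
from xkmir.seqs import MiRNA, gc_fraction, revcomp_rna
from xkmir.synth import (ConfigurationError, GeneratorConfig, SiteMutationSpec,
                         TruthTable, gen_annotations, gen_expression,
                         gen_human_utrome, gen_mirnas, gen_ortholog_pairs,
                         gen_plant_transcriptome, write_synthetic_dataset)
from xkmir.targets import DuplexParams, duplex_mfe, plant_site_score


def test_determinism_under_fixed_seed():
    cfg = GeneratorConfig(seed=1, n_mirnas=5)
    a = [m.sequence for m in gen_mirnas(cfg)]
    b = [m.sequence for m in gen_mirnas(cfg)]
    assert a == b


def test_degenerate_length_range():
    cfg = GeneratorConfig(seed=2, n_mirnas=10, mirna_length_range=(21, 21))
    assert all(len(m) == 21 for m in gen_mirnas(cfg))


def test_gc_range_respected():
    cfg = GeneratorConfig(seed=3, n_mirnas=100, gc_range=(0.6, 0.8))
    for m in gen_mirnas(cfg):
        assert 0.6 - 1e-9 <= gc_fraction(m.sequence) <= 0.8 + 1e-9


def test_invalid_ranges_rejected():
    with pytest.raises(ConfigurationError):
        GeneratorConfig(mirna_length_range=(22, 20))
    with pytest.raises(ConfigurationError):
        GeneratorConfig(gc_range=(0.9, 0.1))
    with pytest.raises(ConfigurationError):
        GeneratorConfig(noise_sd=0.0)
    with pytest.raises(ConfigurationError):
        GeneratorConfig(within_module_correlation=1.0)
    with pytest.raises(ConfigurationError):
        GeneratorConfig(ortholog_identities=(1.2,))


# --- plant transcriptome ---------------------------------------------------


def test_zero_mutation_sites_are_exact_revcomp(small_cfg):
    mirnas = gen_mirnas(small_cfg)
    transcripts, truth = gen_plant_transcriptome(mirnas, small_cfg)
    seqs = {t.id: t.sequence for t in transcripts}
    by_id = {m.id: m for m in mirnas}
    for mirna_id, tid, start, end, kind in truth.planted_targets:
        assert kind == "plant_complement"
        site = seqs[tid][start:end]
        assert site == revcomp_rna(by_id[mirna_id].sequence)
        exp, viol, _ = plant_site_score(by_id[mirna_id], site)
        assert exp == 0.0 and viol == 0


def test_one_nonseed_mismatch_scores_one(small_cfg):
    cfg = dataclasses.replace(
        small_cfg,
        site_mutation_spec=SiteMutationSpec(n_mismatches=1, region="non_seed"),
    )
    mirnas = gen_mirnas(cfg)
    transcripts, truth = gen_plant_transcriptome(mirnas, cfg)
    seqs = {t.id: t.sequence for t in transcripts}
    by_id = {m.id: m for m in mirnas}
    for mirna_id, tid, start, end, _ in truth.planted_targets:
        exp, viol, _ = plant_site_score(by_id[mirna_id], seqs[tid][start:end])
        assert exp == pytest.approx(1.0)
        assert viol == 0


def test_truth_row_counting():
    cfg = GeneratorConfig(seed=4, n_mirnas=3, sites_per_mirna=2,
                          n_plant_transcripts=10)
    mirnas = gen_mirnas(cfg)
    _, truth = gen_plant_transcriptome(mirnas, cfg)
    assert len(truth.planted_targets) == 6


def test_site_longer_than_transcript_rejected():
    cfg = GeneratorConfig(seed=5, transcript_length=18, mirna_length_range=(21, 21))
    with pytest.raises(ConfigurationError):
        gen_plant_transcriptome(gen_mirnas(cfg), cfg)


def test_gu_mutation_spec(small_cfg):
    cfg = dataclasses.replace(
        small_cfg, site_mutation_spec=SiteMutationSpec(n_gu=1, region="non_seed")
    )
    mirnas = gen_mirnas(cfg)
    transcripts, truth = gen_plant_transcriptome(mirnas, cfg)
    seqs = {t.id: t.sequence for t in transcripts}
    by_id = {m.id: m for m in mirnas}
    for mirna_id, tid, start, end, _ in truth.planted_targets:
        exp, _, _ = plant_site_score(by_id[mirna_id], seqs[tid][start:end])
        assert exp == pytest.approx(0.5)


# --- human UTRome ----------------------------------------------------------


def test_planted_human_site_low_mfe():
    mirna = MiRNA("gc70", "GCGUCGGAUGCCGUAGGCAUGC")  # 22 nt, ~70% GC
    res = duplex_mfe(mirna, revcomp_rna(mirna.sequence))
    assert res.mfe < -30.0


def test_human_truth_sites_are_perfect_complements(small_cfg):
    mirnas = gen_mirnas(small_cfg)
    utrs, truth = gen_human_utrome(mirnas, small_cfg)
    seqs = {u.id: u.sequence for u in utrs}
    by_id = {m.id: m for m in mirnas}
    for mirna_id, tid, start, end, kind in truth.planted_targets:
        assert kind == "human_mfe_site"
        assert seqs[tid][start:end] == revcomp_rna(by_id[mirna_id].sequence)


def test_byte_identical_fasta_output(tmp_path, small_cfg):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = write_synthetic_dataset(small_cfg, d1)
    p2 = write_synthetic_dataset(small_cfg, d2)
    for key in p1:
        assert (d1 / f"{key}.fasta").read_bytes() == (d2 / f"{key}.fasta").read_bytes() \
            if key.endswith("fasta") else True
    assert (d1 / "mirnas.fasta").read_bytes() == (d2 / "mirnas.fasta").read_bytes()
    assert (d1 / "expression.tsv").read_bytes() == (d2 / "expression.tsv").read_bytes()
    assert (d1 / "truth.json").read_bytes() == (d2 / "truth.json").read_bytes()


# --- orthologs -------------------------------------------------------------


def test_identical_orthologs(small_cfg):
    cfg = dataclasses.replace(small_cfg, ortholog_identities=(1.0,))
    p_cds, _, h_cds, _, truth = gen_ortholog_pairs(cfg)
    assert p_cds[0].sequence == h_cds[0].sequence
    res = permutation_pvalue(p_cds[0].sequence, h_cds[0].sequence, n_perm=20, seed=1)
    assert res.identity_pct == 100.0
    assert res.p_value == 0.0


def test_ninety_percent_identity(small_cfg):
    cfg = dataclasses.replace(small_cfg, ortholog_identities=(0.9,), cds_length=300)
    p_cds, _, h_cds, _, _ = gen_ortholog_pairs(cfg)
    ungapped_matches = sum(
        a == b for a, b in zip(p_cds[0].sequence, h_cds[0].sequence)
    )
    assert ungapped_matches == 270  # substitution-only: identity is exact
    res = smith_waterman(p_cds[0].sequence, h_cds[0].sequence)
    assert abs(res.identity_pct - 90.0) <= 3.0


def test_unrelated_identity_gives_null_like_pvalues(small_cfg):
    frac_small = 0
    n_rep = 12
    for i in range(n_rep):
        cfg = dataclasses.replace(small_cfg, seed=100 + i,
                                  ortholog_identities=(0.3,), cds_length=240)
        p_cds, _, h_cds, _, _ = gen_ortholog_pairs(cfg)
        res = permutation_pvalue(p_cds[0].sequence, h_cds[0].sequence,
                                 n_perm=40, seed=i)
        frac_small += res.p_value < 0.1
    assert frac_small <= n_rep // 2  # not systematically significant


def test_proteins_are_translations(small_cfg):
    from xkmir.seqs import translate_cds

    p_cds, p_prot, h_cds, h_prot, _ = gen_ortholog_pairs(small_cfg)
    assert p_prot[0].sequence == translate_cds(p_cds[0].sequence).rstrip("*")
    assert h_prot[0].sequence == translate_cds(h_cds[0].sequence).rstrip("*")
    assert "*" not in h_prot[0].sequence  # substitutions never create stops


# --- expression ------------------------------------------------------------


def _pairwise_spearman(values, idx):
    rhos = []
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            rho = stats.spearmanr(values[idx[i]], values[idx[j]]).statistic
            rhos.append(rho)
    return np.array(rhos)


def test_within_module_correlation():
    cfg = GeneratorConfig(seed=8, n_genes=100, n_samples=100, n_modules=2,
                          module_size_range=(10, 12),
                          within_module_correlation=0.9)
    expr, truth = gen_expression(cfg)
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    for genes in truth.modules.values():
        rhos = _pairwise_spearman(expr.values, [gene_pos[g] for g in genes])
        assert np.abs(rhos).mean() > 0.6


def test_background_pairs_uncorrelated():
    cfg = GeneratorConfig(seed=9, n_genes=60, n_samples=100, n_modules=1,
                          module_size_range=(5, 5))
    expr, truth = gen_expression(cfg)
    module_genes = set(truth.modules["module1"])
    bg_idx = [i for i, g in enumerate(expr.gene_ids) if g not in module_genes][:20]
    rhos = _pairwise_spearman(expr.values, bg_idx)
    assert (np.abs(rhos) < 0.3).mean() >= 0.95


def test_noiseless_limit():
    cfg = GeneratorConfig(seed=10, n_genes=40, n_samples=60, n_modules=1,
                          module_size_range=(8, 8),
                          within_module_correlation=0.999)
    expr, truth = gen_expression(cfg)
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    rhos = _pairwise_spearman(expr.values,
                              [gene_pos[g] for g in truth.modules["module1"]])
    assert rhos.min() > 0.95


def test_modules_must_fit():
    with pytest.raises(ConfigurationError):
        gen_expression(GeneratorConfig(n_genes=20, n_modules=3,
                                       module_size_range=(10, 10)))


# --- annotations -----------------------------------------------------------


def test_planted_term_enrichment_p():
    cfg = GeneratorConfig(seed=11, n_genes=500, n_modules=1,
                          module_size_range=(20, 20),
                          enrichment_overlap_fraction=1.0)
    expr, truth = gen_expression(cfg)
    annot, ta = gen_annotations(expr.gene_ids, cfg, truth.modules)
    tid = ta.enriched_terms["module1"]
    _, term_genes = annot.terms[tid]
    module = set(truth.modules["module1"])
    k = len(module & term_genes)
    p = hypergeom_right_tail(k, len(term_genes), len(module), 500)
    assert p < 1e-10


def test_zero_overlap_behaves_like_background():
    cfg = GeneratorConfig(seed=12, n_genes=300, n_modules=1,
                          module_size_range=(15, 15),
                          enrichment_overlap_fraction=0.0)
    expr, truth = gen_expression(cfg)
    annot, ta = gen_annotations(expr.gene_ids, cfg, truth.modules)
    tid = ta.enriched_terms["module1"]
    _, term_genes = annot.terms[tid]
    assert not (set(truth.modules["module1"]) & term_genes)


def test_coverage_flag():
    cfg = GeneratorConfig(seed=13, n_genes=100, n_terms=2,
                          term_size_range=(5, 5), ensure_coverage=True)
    annot, _ = gen_annotations([f"G{i:05d}" for i in range(100)], cfg, {})
    covered = set().union(*(genes for _, genes in annot.terms.values()))
    assert covered == annot.universe


def test_term_larger_than_universe_rejected():
    cfg = GeneratorConfig(seed=14, term_size_range=(50, 50))
    with pytest.raises(ConfigurationError):
        gen_annotations([f"g{i}" for i in range(10)], cfg, {})


# --- truth table -----------------------------------------------------------


def test_truth_validation_and_roundtrip(tmp_path, small_cfg):
    mirnas = gen_mirnas(small_cfg)
    transcripts, truth = gen_plant_transcriptome(mirnas, small_cfg)
    truth.validate({t.id: t.sequence for t in transcripts})
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = TruthTable.from_json(path)
    assert back.planted_targets == truth.planted_targets


def test_truth_rejects_overlapping_modules():
    t = TruthTable(modules={"m1": ["g1", "g2"], "m2": ["g2", "g3"]})
    with pytest.raises(ValueError):
        t.validate()
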