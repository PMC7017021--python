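"""Tests for annotation, filtering, polarization, matching and strata."""

import numpy as np
import pandas as pd
import pytest

from cubdfe.errors import DataError, DomainError
from cubdfe.io import read_genome, read_site_table, write_site_table
from cubdfe.seq import canonical_context, revcomp
from cubdfe.site_matching import (
    annotate_4d_sites,
    annotate_strata,
    apply_filters,
    attach_alleles,
    bootstrap_resample,
    downsample_haplotypes,
    extract_si_sites,
    match_by_state,
    match_controls,
    polarize,
)


def _write_micro_fixture(tmp_path, seq, features):
    fa = tmp_path / "g.fa"
    fa.write_text(f">c1\n{seq}\n")
    gff = tmp_path / "g.gff3"
    lines = ["##gff-version 3"]
    for f in features:
        lines.append("\t".join(str(x) for x in f))
    gff.write_text("\n".join(lines) + "\n")
    return {"c1": seq.upper()}, gff


class TestAnnotate4D:
    def test_alanine_included_met_excluded(self, tmp_path):
        # gene: ATG GCT TAA-free simple CDS on + strand starting at pos 11
        cds = "ATGGCTGGAACC"  # Met Ala Gly Thr
        seq = "T" * 10 + cds + "T" * 10
        feats = [
            ("c1", ".", "gene", 11, 22, ".", "+", ".", "ID=g1"),
            ("c1", ".", "mRNA", 11, 22, ".", "+", ".", "ID=t1;Parent=g1"),
            ("c1", ".", "exon", 11, 22, ".", "+", ".", "ID=e1;Parent=t1"),
            ("c1", ".", "CDS", 11, 22, ".", "+", "0", "ID=c1c;Parent=t1"),
        ]
        genome, gff = _write_micro_fixture(tmp_path, seq, feats)
        out = annotate_4d_sites(genome, str(gff))
        # codons: ATG (no), GCT (Ala 4D, third pos = 16), GGA (Gly, 19), ACC (Thr, 22)
        assert sorted(out.pos) == [16, 19, 22]
        assert set(out.codon) == {"GCT", "GGA", "ACC"}

    def test_cds_not_divisible_by_three_skipped(self, tmp_path):
        seq = "T" * 10 + "ATGGCTA" + "T" * 10
        feats = [
            ("c1", ".", "mRNA", 11, 17, ".", "+", ".", "ID=t1"),
            ("c1", ".", "CDS", 11, 17, ".", "+", "0", "ID=c;Parent=t1"),
        ]
        genome, gff = _write_micro_fixture(tmp_path, seq, feats)
        out = annotate_4d_sites(genome, str(gff))
        assert len(out) == 0

    def test_conflicting_frames_excluded(self, tmp_path):
        cds = "GCTGCAGCT"  # Ala Ala Ala, 4D thirds at 13,16,19
        seq = "T" * 10 + cds + "T" * 10
        feats = [
            ("c1", ".", "mRNA", 11, 19, ".", "+", ".", "ID=t1"),
            ("c1", ".", "CDS", 11, 19, ".", "+", "0", "ID=a;Parent=t1"),
            ("c1", ".", "mRNA", 12, 20, ".", "+", ".", "ID=t2"),
            ("c1", ".", "CDS", 12, 20, ".", "+", "0", "ID=b;Parent=t2"),
        ]
        genome, gff = _write_micro_fixture(tmp_path, seq, feats)
        out = annotate_4d_sites(genome, str(gff))
        # t2's frame is shifted; any position claimed twice inconsistently is gone
        claimed_twice = {13, 16, 19} & set(out.pos)
        for p in claimed_twice:
            assert len(out[out.pos == p]) == 1

    def test_recovers_simulated_truth(self, neutral_dataset, fixture_dir):
        genome = read_genome(fixture_dir / "genome.fa")
        out = annotate_4d_sites(genome, str(fixture_dir / "genes.gff3"))
        truth = neutral_dataset.sites.query("site_class == '4D'")
        assert set(zip(out.chrom, out.pos)) == set(zip(truth.chrom, truth.pos))
        merged = out.merge(truth, on=["chrom", "pos"], suffixes=("_a", "_t"))
        assert (merged.codon_a == merged.codon_t).all()
        assert (merged.strand_a == merged.strand_t).all()


class TestExtractSi:
    def test_recovers_simulated_truth(self, neutral_dataset, fixture_dir):
        genome = read_genome(fixture_dir / "genome.fa")
        out = extract_si_sites(genome, str(fixture_dir / "genes.gff3"))
        truth = neutral_dataset.sites.query("site_class == 'SI'")
        assert set(zip(out.chrom, out.pos)) == set(zip(truth.chrom, truth.pos))

    @pytest.mark.parametrize(
        "intron_len,expected", [(86, 0), (100, 84), (16, 0)]
    )
    def test_length_rule(self, tmp_path, intron_len, expected):
        exon1 = "GCTGCAGCA"
        intron = "T" * intron_len
        exon2 = "GCCGCGGCA"
        seq = "A" * 10 + exon1 + intron + exon2 + "A" * 10
        s1, e1 = 11, 19
        s2 = e1 + intron_len + 1
        e2 = s2 + 8
        feats = [
            ("c1", ".", "mRNA", s1, e2, ".", "+", ".", "ID=t1"),
            ("c1", ".", "exon", s1, e1, ".", "+", ".", "ID=x1;Parent=t1"),
            ("c1", ".", "exon", s2, e2, ".", "+", ".", "ID=x2;Parent=t1"),
            ("c1", ".", "CDS", s1, e1, ".", "+", "0", "ID=ca;Parent=t1"),
            ("c1", ".", "CDS", s2, e2, ".", "+", "0", "ID=cb;Parent=t1"),
        ]
        genome, gff = _write_micro_fixture(tmp_path, seq, feats)
        out = extract_si_sites(genome, str(gff))
        assert len(out) == expected

    def test_inclusive_rule_configurable(self, tmp_path):
        intron_len = 86
        seq = "A" * 10 + "GCTGCAGCA" + "T" * intron_len + "GCCGCGGCA" + "A" * 10
        feats = [
            ("c1", ".", "mRNA", 11, 19 + intron_len + 9, ".", "+", ".", "ID=t1"),
            ("c1", ".", "exon", 11, 19, ".", "+", ".", "ID=x1;Parent=t1"),
            ("c1", ".", "exon", 20 + intron_len, 19 + intron_len + 9, ".", "+", ".",
             "ID=x2;Parent=t1"),
        ]
        genome, gff = _write_micro_fixture(tmp_path, seq, feats)
        out = extract_si_sites(genome, str(gff), comparison="<=")
        assert len(out) == 86 - 16


def _basic_sites():
    return pd.DataFrame(
        {
            "chrom": ["c1"] * 4,
            "pos": [100, 111, 150, 300],
            "site_class": ["4D", "SI", "4D", "SI"],
            "ancestral": ["A", "C", "G", "T"],
            "derived": [".", "T", "A", "."],
            "derived_count": [0, 5, 8, 0],
            "n_haplotypes": [160] * 4,
            "context3": ["CAG", "ACT", "TGA", "CTA"],
            "gene_id": ["g1"] * 4,
            "codon": ["GCA", ".", "CCG", "."],
            "strand": ["+"] * 4,
        }
    )


class TestFilters:
    def test_indel_window_boundary_inclusive(self):
        sites = _basic_sites()
        indels = pd.DataFrame(
            [("c1", 109, 110, "i")], columns=["chrom", "start", "end", "name"]
        )  # 1-based indel position 110
        out = apply_filters(sites, indels=indels, indel_window=10)
        # pos 100 and 111 are within 10 bp of position 110 -> removed
        assert sorted(out.pos) == [150, 300]
        assert out.attrs["filter_counts"]["near_indel"] == 2

    def test_triallelic_removed(self):
        sites = _basic_sites()
        sites["n_alleles"] = [2, 3, 2, 2]
        out = apply_filters(sites)
        assert 111 not in set(out.pos)
        assert out.attrs["filter_counts"]["multiallelic"] == 1

    def test_low_quality_flag(self):
        sites = _basic_sites()
        sites["low_quality"] = [False, True, False, False]
        out = apply_filters(sites)
        assert sorted(out.pos) == [100, 150, 300]

    def test_clean_table_unchanged(self):
        sites = _basic_sites()
        sites["low_quality"] = False
        sites["n_alleles"] = 2
        out = apply_filters(sites, indels=pd.DataFrame(
            columns=["chrom", "start", "end", "name"]))
        assert len(out) == len(sites)

    def test_idempotent(self):
        sites = _basic_sites()
        sites["low_quality"] = [False, True, False, False]
        once = apply_filters(sites)
        twice = apply_filters(once)
        pd.testing.assert_frame_equal(once, twice)


class TestDownsample:
    def test_at_target_unchanged(self):
        sites = _basic_sites()
        out = downsample_haplotypes(sites, target_ns=160, seed=1)
        assert list(out.derived_count) == list(sites.derived_count)

    def test_monomorphic_invariant(self):
        sites = _basic_sites()
        sites["n_haplotypes"] = 200
        sites["derived_count"] = 0
        sites["derived"] = "."
        out = downsample_haplotypes(sites, target_ns=160, seed=1)
        assert (out.derived_count == 0).all()

    def test_below_target_dropped(self):
        sites = _basic_sites()
        sites.loc[0, "n_haplotypes"] = 100
        out = downsample_haplotypes(sites, target_ns=160, seed=1)
        assert 100 not in set(out.pos)

    def test_hypergeometric_mean(self):
        n = 3000
        sites = pd.DataFrame(
            {
                "chrom": "c1",
                "pos": np.arange(n),
                "site_class": "4D",
                "ancestral": "A",
                "derived": "G",
                "derived_count": 100,
                "n_haplotypes": 200,
                "context3": "CAG",
                "gene_id": "g",
                "codon": "GCA",
                "strand": "+",
            }
        )
        out = downsample_haplotypes(sites, target_ns=160, seed=5)
        # hypergeometric mean 160 * 100/200 = 80
        se = np.sqrt(out.derived_count.var() / len(out))
        assert abs(out.derived_count.mean() - 80) < 3 * se

    def test_target_too_small(self):
        with pytest.raises(DomainError):
            downsample_haplotypes(_basic_sites(), target_ns=1)


class TestPolarize:
    def _table(self, outgroup, reference="A"):
        t = _basic_sites().iloc[[1]].copy()  # polymorphic site, A? no: C/T
        t["ancestral"] = "A"
        t["derived"] = "G"
        t["context3"] = "CAT"
        t["derived_count"] = 40
        t["outgroup"] = outgroup
        t["reference"] = reference
        return t.reset_index(drop=True)

    def test_outgroup_matches_first_allele(self):
        out = polarize(self._table("A"))
        assert out.ancestral[0] == "A" and out.derived_count[0] == 40
        assert out.polarization[0] == "outgroup"

    def test_outgroup_matches_second_allele_swaps(self):
        out = polarize(self._table("G"))
        assert out.ancestral[0] == "G" and out.derived[0] == "A"
        assert out.derived_count[0] == 120
        assert out.context3[0] == "CGT"

    def test_ambiguous_uses_reference(self):
        out = polarize(self._table("C", reference="G"))
        assert out.polarization[0] == "ambiguous"
        assert out.ancestral[0] == "G" and out.derived_count[0] == 120

    def test_monomorphic_keeps_observed(self):
        t = self._table("C")
        t["derived"] = "."
        t["derived_count"] = 0
        out = polarize(t)
        assert out.ancestral[0] == "A"
        assert out.polarization[0] == "monomorphic"

    def test_non_nucleotide_error(self):
        t = self._table("A")
        t["ancestral"] = "N"
        t["derived"] = "."
        with pytest.raises(DataError):
            polarize(t)


def _matchable_sites():
    rows = []
    # one 4D site with context ACG at pos 1000
    rows.append(("c1", 1000, "4D", "C", ".", 0, "ACG", "GCC", "+"))
    # eligible SI: reverse complement context CGT at distance 500
    rows.append(("c1", 1500, "SI", "G", ".", 0, "CGT", ".", "+"))
    # ineligible SI: distance 1001
    rows.append(("c1", 2001, "SI", "C", ".", 0, "ACG", ".", "+"))
    # ineligible SI: wrong context
    rows.append(("c1", 1100, "SI", "C", ".", 0, "TCG", ".", "+"))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "site_class", "ancestral", "derived",
                 "derived_count", "context3", "codon", "strand"],
    ).assign(n_haplotypes=160, gene_id="g1")


class TestMatchControls:
    def test_strand_blind_transform_and_distance(self):
        reps = match_controls(_matchable_sites(), n_replicates=3, seed=1)
        for rep in reps:
            assert len(rep) == 1
            pair = rep.pairs()
            assert pair.pos_si[0] == 1500  # only the revcomp candidate

    def test_replicates_share_identical_4d_set(self, neutral_dataset):
        reps = match_controls(neutral_dataset.sites, n_replicates=10, seed=2)
        first = reps[0].fourd
        for rep in reps[1:]:
            assert np.array_equal(rep.fourd, first)

    def test_pair_constraints_hold(self, neutral_dataset):
        reps = match_controls(neutral_dataset.sites, n_replicates=3, seed=3)
        sites = neutral_dataset.sites
        for rep in reps:
            f = sites.iloc[rep.fourd]
            s = sites.iloc[rep.si]
            assert (f.chrom.to_numpy() == s.chrom.to_numpy()).all()
            assert (np.abs(f.pos.to_numpy() - s.pos.to_numpy()) <= 1000).all()
            kf = [canonical_context(c) for c in f.context3]
            ks = [canonical_context(c) for c in s.context3]
            assert kf == ks

    def test_deterministic(self, neutral_dataset):
        a = match_controls(neutral_dataset.sites, n_replicates=2, seed=9)
        b = match_controls(neutral_dataset.sites, n_replicates=2, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.si, y.si)

    def test_empty_input_error(self):
        sites = _matchable_sites()
        with pytest.raises(DataError):
            match_controls(sites[sites.site_class == "4D"])


class TestMatchByState:
    def test_position_1_change_rejected(self, neutral_dataset):
        with pytest.raises(DomainError):
            match_by_state(neutral_dataset.sites, "CCC", "ACC")

    def test_state_composition(self, neutral_dataset):
        sites = neutral_dataset.sites
        rep = match_by_state(sites, "CCC", "CCA", seed=4)
        f = sites.iloc[rep.fourd]
        s = sites.iloc[rep.si]
        assert (f.codon == "CCC").all()
        # every matched SI is monomorphic or carries the same base change
        # (up to strand transforms)
        for (_, frow), (_, srow) in zip(f.iterrows(), s.iterrows()):
            if srow.derived == ".":
                assert canonical_context(srow.context3) == canonical_context(
                    frow.context3
                )
            else:
                d_ref = "A" if frow.strand == "+" else "T"
                assert canonical_context(
                    srow.context3, srow.derived
                ) == canonical_context(frow.context3, d_ref)


class TestBootstrapResample:
    def test_deterministic(self, neutral_dataset):
        rep = match_controls(neutral_dataset.sites, n_replicates=1, seed=5)[0]
        a = bootstrap_resample(rep, seed=1)
        b = bootstrap_resample(rep, seed=1)
        assert np.array_equal(a.fourd, b.fourd) and np.array_equal(a.si, b.si)

    def test_single_pair(self):
        rep = match_controls(_matchable_sites(), n_replicates=1, seed=1)[0]
        out = bootstrap_resample(rep, seed=0)
        assert len(out) == 1 and out.fourd[0] == rep.fourd[0]

    def test_unbiasedness(self, neutral_dataset):
        rep = match_controls(neutral_dataset.sites, n_replicates=1, seed=6)[0]
        poly = (rep.sites.derived_count.to_numpy() > 0)
        orig = poly[rep.fourd].mean()
        means = [
            poly[bootstrap_resample(rep, seed=s).fourd].mean() for s in range(300)
        ]
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - orig) < 3 * se


class TestStrata:
    def test_bed_membership_half_open(self):
        sites = _basic_sites()
        bed = pd.DataFrame(
            [("c1", 99, 150, "s")], columns=["chrom", "start", "end", "name"]
        )
        out = annotate_strata(sites, {"x": {"kind": "bed", "intervals": bed}})
        # 0-based half-open [99, 150) = 1-based 100..150
        assert list(out.stratum_x) == [True, True, True, False]

    def test_malformed_bed_reports_line(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("c1\t10\n")
        with pytest.raises(DataError, match="line 1"):
            annotate_strata(
                _basic_sites(), {"x": {"kind": "bed", "path": str(bad)}}
            )

    def test_exon_position_quartiles(self):
        sites = _basic_sites()
        sites["exon_rel_pos"] = [0.09, np.nan, 0.5, np.nan]
        out = annotate_strata(sites, {"pos": {"kind": "exon_position"}})
        assert out.exon_position_group[0] == "start"
        assert out.exon_position_group[2] == "middle"

    def test_simulated_strata_match_manifest(self, tmp_path):
        from cubdfe.synthetic_data import SyntheticConfig, simulate_site_table

        cfg = SyntheticConfig(
            n_genes=10, ne=200, ns=20, strata_fractions={"tf": 0.5}, seed=21
        )
        ds = simulate_site_table(cfg)
        out = annotate_strata(
            ds.sites, {"tf": {"kind": "bed", "intervals": ds.strata["tf"]}}
        )
        member_genes = set(out.loc[out.stratum_tf, "gene_id"])
        truth_genes = set(ds.strata["tf"]["name"])
        assert member_genes == truth_genes

    def test_recombination_tertiles(self):
        sites = _basic_sites()
        win = pd.DataFrame(
            {
                "chrom": ["c1"] * 3,
                "start": [0, 120, 200],
                "end": [120, 200, 400],
                "rate": [0.5, 2.0, 5.0],
            }
        )
        out = annotate_strata(
            sites, {"rec": {"kind": "recombination", "windows": win}}
        )
        assert list(out.recomb_group) == ["low", "low", "medium", "high"]


def test_attach_alleles_roundtrip(neutral_dataset, fixture_dir):
    genome = read_genome(fixture_dir / "genome.fa")
    fourd = annotate_4d_sites(genome, str(fixture_dir / "genes.gff3"))
    table = read_site_table(fixture_dir / "sites.tsv")
    merged = attach_alleles(fourd, table)
    assert len(merged) == len(fourd)
    assert "derived_count" in merged.columns
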