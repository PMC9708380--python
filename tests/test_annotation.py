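import math

import numpy as np
import pandas as pd
import pytest

from hgtflow.annotation import (
    app_gene_status,
    enrichment_test,
    finalize_labels,
    fold_enrichment,
    load_marker_hits,
    marker_genes,
    presence_from_blast,
    read_blast6,
)
from hgtflow.genome_io import CodonUsage
from hgtflow.jscb import GeneCluster


def make_cluster(cid, genes, klass="atypical", genome="G1"):
    return GeneCluster(
        cluster_id=cid,
        genome_id=genome,
        member_gene_ids=list(genes),
        pooled=CodonUsage(np.zeros(61, dtype=np.int64)),
        compositional_class=klass,
    )


def hypergeom_upper_tail_enum(pop, succ, draws, observed):
    """Exhaustive oracle: P(X >= observed) by direct enumeration."""
    denom = math.comb(pop, draws)
    num = sum(
        math.comb(succ, i) * math.comb(pop - succ, draws - i)
        for i in range(observed, min(succ, draws) + 1)
    )
    return num / denom


class TestMarkerLoading:
    def test_tsv_boundary_inclusive(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "gene_id\tfamily\te_value\n"
            "g1\ttransposase\t0.01\n"
            "g2\tintegrase\t0.02\n"
            "g3\tphage\t1e-10\n"
            "g3\tplasmid\t1e-5\n"
        )
        hits = load_marker_hits(p)
        assert marker_genes(hits) == {"g1", "g3"}  # 0.01 kept, 0.02 dropped, g3 deduped

    def test_domtblout_format(self, tmp_path):
        p = tmp_path / "m.domtblout"
        cols = ["transposase_fam", "PF00001", "200", "geneA", "-", "450"]
        row = " ".join(cols + ["1e-5"] + ["0"] * 16)
        p.write_text("# comment line\n" + row + "\n")
        hits = load_marker_hits(p)
        assert marker_genes(hits) == {"geneA"}
        (h,) = hits
        assert h.marker_family == "transposase_fam"

    def test_unparseable_rows_skipped(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("g1\ttransposase\tnot_a_number\ng2\tphage\t0.001\n")
        assert marker_genes(load_marker_hits(p)) == {"g2"}

    def test_e_max_monotonicity(self, tmp_path, rng):
        p = tmp_path / "m.tsv"
        rows = [f"g{i}\tphage\t{10.0 ** rng.uniform(-6, 0)}" for i in range(50)]
        p.write_text("\n".join(rows) + "\n")
        previous: set[str] = set()
        for e_max in (1e-4, 1e-2, 1e-1, 1.0):
            current = marker_genes(load_marker_hits(p, e_max=e_max))
            assert previous.issubset(current)
            previous = current


class TestFoldEnrichment:
    @pytest.mark.parametrize(
        "mc, sc, mr, sr, expected",
        [(4, 10, 10, 1000, 40.0), (5, 50, 10, 100, 1.0), (0, 10, 5, 100, 0.0)],
    )
    def test_formula(self, mc, sc, mr, sr, expected):
        assert fold_enrichment(mc, sc, mr, sr) == pytest.approx(expected)

    def test_zero_reference_markers(self):
        assert fold_enrichment(3, 10, 0, 100) == math.inf
        assert fold_enrichment(0, 10, 0, 100) == 1.0

    def test_zero_size_is_error(self):
        with pytest.raises(ValueError):
            fold_enrichment(1, 0, 1, 10)


class TestEnrichmentTest:
    def test_worked_example(self):
        """5-gene cluster with 3 markers vs 15-gene native with 1: p = 496/15504."""
        cluster = make_cluster("GG1_Cl_2", [f"c{i}" for i in range(5)])
        native = make_cluster("GG1_Cl_1", [f"n{i}" for i in range(15)], "typical")
        markers = {"c0", "c1", "c2", "n0"}
        res = enrichment_test(cluster, native, markers)
        assert res.p_hypergeom == pytest.approx(496 / 15504, rel=1e-12)
        assert res.enriched

    def test_no_markers_not_enriched(self):
        cluster = make_cluster("GG1_Cl_2", ["c0", "c1"])
        native = make_cluster("GG1_Cl_1", [f"n{i}" for i in range(10)], "typical")
        res = enrichment_test(cluster, native, {"n0"})
        assert res.p_hypergeom == pytest.approx(1.0)
        assert not res.enriched

    def test_equal_rates_blocked_by_fold_cutoff(self):
        cluster = make_cluster("GG1_Cl_2", ["c0", "c1"])
        native = make_cluster("GG1_Cl_1", ["n0", "n1"], "typical")
        res = enrichment_test(cluster, native, {"c0", "c1", "n0", "n1"})
        assert res.fold_vs_native == pytest.approx(1.0)
        assert not res.enriched

    def test_matches_enumeration_small_populations(self, rng):
        """scipy hypergeometric tail equals brute-force enumeration, pop <= 30."""
        for _ in range(300):
            n_c = int(rng.integers(1, 16))
            n_n = int(rng.integers(1, 16))
            pop = n_c + n_n
            if pop > 30:
                continue
            cluster = make_cluster("GG1_Cl_2", [f"c{i}" for i in range(n_c)])
            native = make_cluster("GG1_Cl_1", [f"n{i}" for i in range(n_n)], "typical")
            all_genes = cluster.member_gene_ids + native.member_gene_ids
            k = int(rng.integers(0, pop + 1))
            markers = set(rng.choice(all_genes, size=k, replace=False))
            res = enrichment_test(cluster, native, markers)
            observed = len(set(cluster.member_gene_ids) & markers)
            expected = hypergeom_upper_tail_enum(pop, len(markers), n_c, observed)
            assert res.p_hypergeom == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_empty_native_is_error(self):
        cluster = make_cluster("GG1_Cl_2", ["c0"])
        native = make_cluster("GG1_Cl_1", [], "typical")
        with pytest.raises(ValueError):
            enrichment_test(cluster, native, set())


class TestPresenceFromBlast:
    def blast_df(self, rows):
        return pd.DataFrame(
            rows,
            columns=["qseqid", "sseqid", "pident", "length", "qstart", "qend", "qlen", "evalue", "bitscore"],
        )

    def test_fraction_and_coverage_boundary(self):
        rows = [
            ["g1", "rel1", 80.0, 70, 1, 70, 100, 1e-20, 100.0],  # qcov 0.70 -> counted
            ["g1", "rel2", 80.0, 69, 1, 69, 100, 1e-20, 100.0],  # qcov 0.69 -> not
        ]
        fr = presence_from_blast(self.blast_df(rows), relatives=set(f"rel{i}" for i in range(1, 11)), rank="species")
        assert fr["g1"] == pytest.approx(0.10)

    def test_rank_specific_identity_cutoffs(self):
        rows = [["g1", "rel1", 50.0, 80, 1, 80, 100, 1e-20, 100.0]]
        df = self.blast_df(rows)
        rel = {"rel1"}
        assert presence_from_blast(df, rel, "genus")["g1"] == pytest.approx(1.0)
        assert presence_from_blast(df, rel, "species")["g1"] == pytest.approx(0.0)

    def test_no_relatives_returns_missing(self):
        assert presence_from_blast(self.blast_df([]), set(), "species") == {}

    def test_read_blast6_computes_qcov(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("g1\trel1\t85.5\t70\t1\t70\t100\t1e-30\t120\n")
        df = read_blast6(p)
        assert df["qcov"].iloc[0] == pytest.approx(0.70)


class TestAppCascade:
    # 12-profile truth table for the species->genus->family cascade
    PROFILES = [
        ({"species": 0.20}, "aberrant", "species"),
        ({"species": 0.30}, "aberrant", "species"),  # boundary: 'only 30%' inclusive
        ({"species": 0.31}, "not_aberrant", "species"),
        ({"species": 0.80}, "not_aberrant", "species"),  # 0.80 does not escalate
        ({"species": 0.90, "genus": 0.90, "family": 0.90}, "not_aberrant", "family"),
        ({"species": 0.90, "genus": 0.20}, "aberrant", "genus"),  # ancient transfer
        ({"species": 0.90, "genus": 0.90, "family": 0.10}, "aberrant", "family"),
        ({"species": 0.81, "genus": 0.50}, "not_aberrant", "genus"),
        ({"species": None, "genus": 0.10}, "aberrant", "genus"),
        ({"species": None, "genus": None, "family": None}, "undetermined", "none"),
        ({"species": 0.0}, "aberrant", "species"),
        ({"species": 1.0, "genus": 1.0, "family": 1.0}, "not_aberrant", "family"),
    ]

    @pytest.mark.parametrize("fractions, status, rank", PROFILES)
    def test_truth_table(self, fractions, status, rank):
        call = app_gene_status("g", fractions)
        assert call.status == status
        assert call.rank_evaluated == rank


class TestFinalizeLabels:
    def build(self):
        native = make_cluster("GG1_Cl_1", [f"n{i}" for i in range(20)], "typical")
        atyp = make_cluster("GG1_Cl_2", [f"a{i}" for i in range(10)])
        return native, atyp

    def label(self, enriched, aberrant_count, determinable=10, has_relatives=True):
        from hgtflow.annotation import EnrichmentResult, PhyleticCall

        native, atyp = self.build()
        res = EnrichmentResult("GG1_Cl_2", 3, 2.0, None, 0.01 if enriched else 0.5, enriched)
        calls = {}
        for i in range(determinable):
            status = "aberrant" if i < aberrant_count else "not_aberrant"
            calls[f"a{i}"] = PhyleticCall(f"a{i}", "species", {}, status)
        clusters = finalize_labels(
            [native, atyp], {"GG1_Cl_2": res}, calls, has_relatives=has_relatives
        )
        return clusters[0], clusters[1]

    def test_typical_is_native(self):
        native, _ = self.label(False, 0)
        assert native.label == "native" and native.evidence_tier is None

    def test_enriched_and_aberrant_tier3(self):
        _, atyp = self.label(True, 8)
        assert atyp.label == "alien" and atyp.evidence_tier == 3

    def test_enriched_only_tier2(self):
        _, atyp = self.label(True, 0)
        assert atyp.label == "alien" and atyp.evidence_tier == 2

    def test_majority_aberrant_tier2(self):
        _, atyp = self.label(False, 6)
        assert atyp.label == "alien" and atyp.evidence_tier == 2

    def test_half_aberrant_is_not_majority(self):
        _, atyp = self.label(False, 5)  # 5/10 is not a strict majority
        assert atyp.label == "native" and atyp.evidence_tier == 1

    def test_no_aberrant_stays_native(self):
        _, atyp = self.label(False, 0)
        assert atyp.label == "native" and atyp.evidence_tier == 1

    def test_no_relatives_defaults_native(self):
        _, atyp = self.label(False, 10, has_relatives=False)
        assert atyp.label == "native"

    def test_missing_enrichment_is_error(self):
        native, atyp = self.build()
        with pytest.raises(ValueError, match="missing enrichment"):
            finalize_labels([native, atyp], {}, {})


class TestEnrichmentRecoverySynthetic:
    def test_ten_fold_marker_rate_detected(self, rng):
        """Alien clusters of >=10 genes at 10x marker density are flagged."""
        from hgtflow.simulate import synth_marker_hits, CommunityTruth

        n_hits = 0
        n_trials = 40
        for t in range(n_trials):
            genes_native = [f"t{t}n{i}" for i in range(300)]
            genes_alien = [f"t{t}a{i}" for i in range(12)]
            truth = CommunityTruth(
                gene_origin={**{g: "native" for g in genes_native},
                             **{g: "alien:d" for g in genes_alien}}
            )
            hits = synth_marker_hits(truth, rate_native=0.05, rate_alien=0.5, seed=rng)
            ids = set(hits["gene_id"])
            native = make_cluster("GG1_Cl_1", genes_native, "typical")
            alien = make_cluster("GG1_Cl_2", genes_alien)
            if enrichment_test(alien, native, ids).enriched:
                n_hits += 1
        assert n_hits / n_trials >= 0.9
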