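"""Filtering/Selection: config handling, the bitscore-200 partition rule,
and end-to-end runs against locally built toy BLAST+ databases."""

import pytest

from editorf import (
    ConfigError,
    PlantedOrfSpec,
    TriageConfig,
    blast_tools_available,
    bitscore_bin,
    extract_orfs,
    load_config,
    make_genome,
    make_toy_blast_dbs,
    partition_candidates,
    run_est_search,
    run_protein_search,
)
from editorf.triage import BlastHitSummary

needs_blast = pytest.mark.skipif(
    not blast_tools_available(), reason="NCBI BLAST+ executables not on PATH"
)


def hit(qid, score, organism=None, taxid=None, program="blastp"):
    return BlastHitSummary(
        query_id=qid, best_bitscore=score, best_hit_accession="s",
        program=program, best_hit_organism=organism, best_hit_taxid=taxid,
    )


def cands(n):
    genome, truth = make_genome(
        [PlantedOrfSpec("fwd", "edited", "main", 150 + 7 * i) for i in range(n)],
        background_length=1000 + n * 600,
        seed=21,
    )
    out = extract_orfs(genome, theta_len=300)
    assert len(out) == n
    return out


class TestConfig:
    def test_properties_roundtrip(self, tmp_path):
        p = tmp_path / "data.properties"
        p.write_text(
            "# comment\nblastp_path = blastp\nprotein_db=/tmp/db\nself_name=Oryza sativa\n"
        )
        cfg = load_config(p)
        assert cfg.blastp_path == "blastp"
        assert cfg.protein_db == "/tmp/db"
        assert cfg.self_name == "Oryza sativa"

    def test_malformed_line_aborts(self, tmp_path):
        p = tmp_path / "bad.properties"
        p.write_text("blastp_path blastp\n")
        with pytest.raises(ConfigError, match="key=value"):
            load_config(p)

    def test_missing_db_names_config_key(self):
        cfg = TriageConfig(protein_db="/nonexistent/db")
        with pytest.raises(ConfigError, match="protein_db"):
            run_protein_search(cands(1), cfg)

    def test_missing_executable_names_config_key(self, tmp_path):
        cfg = TriageConfig(blastp_path="/nonexistent/blastp", protein_db=str(tmp_path))
        with pytest.raises(ConfigError, match="blastp_path"):
            run_protein_search(cands(1), cfg)


class TestPartition:
    def test_threshold_boundary_inclusive(self):
        c = cands(1)
        parts = partition_candidates(
            [hit(c[0].id, 200.0, organism="Oryza sativa", taxid="4530")],
            c, self_taxid="4530",
        )
        assert parts["to_drop"] == c

    def test_below_threshold_is_unknown(self):
        c = cands(1)
        parts = partition_candidates(
            [hit(c[0].id, 199.9, organism="Oryza sativa", taxid="4530")],
            c, self_taxid="4530",
        )
        assert parts["no_known_protein"] == c

    def test_other_organism_retained(self):
        c = cands(1)
        parts = partition_candidates(
            [hit(c[0].id, 266.0, organism="Oryza nivara", taxid="4536")],
            c, self_taxid="4530", self_name="Oryza sativa",
        )
        assert parts["known_other_organism"] == c

    def test_name_prefix_match_when_no_taxid(self):
        c = cands(1)
        parts = partition_candidates(
            [hit(c[0].id, 250.0, organism="Oryza sativa Indica Group")],
            c, self_name="Oryza sativa",
        )
        assert parts["to_drop"] == c

    def test_no_hit_is_unknown_and_partition_is_exhaustive(self):
        c = cands(4)
        parts = partition_candidates(
            [hit(c[0].id, 300.0, organism="Zea mays"),
             hit(c[1].id, 300.0, organism="Oryza sativa")],
            c, self_name="Oryza sativa",
        )
        all_ids = sorted(x.id for xs in parts.values() for x in xs)
        assert all_ids == sorted(x.id for x in c)
        assert [x.id for x in parts["known_other_organism"]] == [c[0].id]
        assert [x.id for x in parts["to_drop"]] == [c[1].id]
        assert {x.id for x in parts["no_known_protein"]} == {c[2].id, c[3].id}

    def test_raising_threshold_never_unmasks(self):
        c = cands(3)
        hits = [hit(c[0].id, 150.0, "Zea mays"), hit(c[1].id, 250.0, "Zea mays")]
        for t1, t2 in [(100, 200), (200, 300)]:
            lo = partition_candidates(hits, c, self_name="Oryza sativa", threshold=t1)
            hi = partition_candidates(hits, c, self_name="Oryza sativa", threshold=t2)
            assert {x.id for x in lo["no_known_protein"]} <= {x.id for x in hi["no_known_protein"]}

    def test_bitscore_bins(self):
        assert bitscore_bin(hit("q", 266.0)) == "ge200"
        assert bitscore_bin(hit("q", 200.0)) == "ge200"
        assert bitscore_bin(hit("q", 199.9)) == "80to200"
        assert bitscore_bin(hit("q", 80.0)) == "80to200"
        assert bitscore_bin(hit("q", 79.9)) == "below80"
        assert bitscore_bin(None) == "none"


@pytest.fixture(scope="module")
def toy(tmp_path_factory):
    candidates = cands(8)
    out = tmp_path_factory.mktemp("toydb")
    if not blast_tools_available():
        pytest.skip("NCBI BLAST+ executables not on PATH")
    prot_db, est_db, expected = make_toy_blast_dbs(candidates, out)
    cfg = TriageConfig(
        protein_db=prot_db, est_db=est_db,
        self_taxid="4530", self_name="Oryza sativa",
    )
    return candidates, cfg, expected


@needs_blast
class TestWithLocalBlast:

    def test_self_hit_found(self, toy):
        candidates, cfg, expected = toy
        summaries = run_protein_search(candidates, cfg)
        in_db = {cid for cid, role in expected.items()
                 if role in ("to_drop", "known_other_organism")}
        got = {s.query_id for s in summaries if s.best_bitscore >= 200}
        assert got >= in_db

    def test_empty_candidate_list_errors(self, toy):
        _, cfg, _ = toy
        with pytest.raises(ValueError, match="no candidates"):
            run_protein_search([], cfg)

    def test_constructed_partition_recovered(self, toy):
        candidates, cfg, expected = toy
        summaries = run_protein_search(candidates, cfg)
        parts = partition_candidates(
            summaries, candidates, self_taxid=cfg.self_taxid, self_name=cfg.self_name
        )
        got = {c.id: name for name, cs in parts.items() for c in cs}
        want = {
            cid: ("no_known_protein" if role.startswith("no_known_protein") else role)
            for cid, role in expected.items()
        }
        assert got == want

    def test_est_screen_finds_planted_transcripts_only(self, toy):
        candidates, cfg, expected = toy
        unknown = [c for c in candidates if expected[c.id].startswith("no_known_protein")]
        summaries = run_est_search(unknown, cfg)
        with_est = {s.query_id for s in summaries if s.best_bitscore >= 80}
        planted = {cid for cid, role in expected.items() if role == "no_known_protein_est"}
        assert with_est == planted

    def test_best_of_duplicated_subjects_is_single_summary(self, tmp_path):
        from editorf.sequence_io import write_fasta
        from editorf.fixtures import _makeblastdb

        c = cands(1)[0]
        fa = tmp_path / "dup.faa"
        write_fasta(
            [("dup1 copy one [Zea mays]", c.aa_seq),
             ("dup2 copy two [Zea mays]", c.aa_seq),
             ("frag1 fragment [Zea mays]", c.aa_seq[: len(c.aa_seq) // 2])],
            fa,
        )
        _makeblastdb(fa, str(tmp_path / "dupdb"), "prot", None)
        cfg = TriageConfig(protein_db=str(tmp_path / "dupdb"))
        summaries = run_protein_search([c], cfg)
        assert len(summaries) == 1
        s = summaries[0]
        assert s.best_hit_accession in ("dup1", "dup2")
        assert s.best_hit_organism == "Zea mays"
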