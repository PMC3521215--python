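"""BLAT hit filtering, best-hit assignment and variant pooling."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stratdeg as sd
from stratdeg.est_assignment import (
    assign_best_hits,
    attach_libraries,
    hits_from_psl,
    read_gene_map,
    read_psl,
)


def _hit(est="E1", tx="T1", matches=100, mism=0, length=100, rank=0):
    return sd.AlignmentHit(est_id=est, transcript_id=tx, matches=matches,
                           mismatches=mism, aligned_length=length,
                           encounter_rank=rank)


class TestPercentIdentity:
    @pytest.mark.parametrize("matches,length,expected", [
        (100, 100, 100.0),
        (95, 100, 95.0),
        (57, 60, 95.0),
    ])
    def test_span_identity(self, matches, length, expected):
        hit = _hit(matches=matches, length=length)
        assert sd.percent_identity(hit) == pytest.approx(expected)

    def test_zero_span_undefined(self):
        with pytest.raises(sd.ValidationError):
            sd.percent_identity(_hit(matches=0, length=0))

    def test_mismatch_variant(self):
        hit = _hit(matches=95, mism=5, length=120)
        assert sd.percent_identity(hit, method="mismatch") == pytest.approx(95.0)


class TestBestHit:
    def test_highest_identity_wins(self):
        hits = [_hit(tx="A", matches=144, length=150, rank=0),   # 96.0%
                _hit(tx="B", matches=191, length=200, rank=1)]   # 95.5%
        assert sd.assign_best_hit(hits) == "A"

    def test_below_identity_threshold_unassigned(self):
        assert sd.assign_best_hit([_hit(matches=470, length=500)]) is None  # 94%

    def test_exact_95_percent_is_inclusive(self):
        assert sd.assign_best_hit([_hit(matches=95, length=100)]) == "T1"

    def test_identity_tie_goes_to_first_encountered(self):
        hits = [_hit(tx="A", matches=291, length=300, rank=2),   # 97.0%
                _hit(tx="B", matches=194, length=200, rank=1)]   # 97.0%
        assert sd.assign_best_hit(hits) == "B"

    def test_short_alignment_rejected(self):
        assert sd.assign_best_hit([_hit(matches=99, length=99)]) is None
        assert sd.assign_best_hit([_hit(matches=100, length=100)]) == "T1"

    def test_empty_hit_list_unassigned(self):
        assert sd.assign_best_hit([]) is None

    def test_mixed_est_ids_rejected(self):
        with pytest.raises(sd.ValidationError):
            sd.assign_best_hit([_hit(est="E1"), _hit(est="E2")])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.permutations(list(range(6))))
    def test_order_invariance_with_preserved_ranks(self, order):
        base = [
            _hit(tx=f"T{i}", matches=280 + i, length=300, rank=i)
            for i in range(6)
        ]
        shuffled = [base[i] for i in order]
        assert sd.assign_best_hit(shuffled) == sd.assign_best_hit(base)

    def test_raising_min_identity_is_monotone(self, small_corpus):
        hits = hits_from_psl(small_corpus.psl)
        at95, _ = assign_best_hits(hits, min_identity=95.0)
        at96, _ = assign_best_hits(hits, min_identity=96.0)
        assert set(at96["est_id"]) <= set(at95["est_id"])


class TestCollapse:
    def test_variant_pooling_sums_counts(self):
        df = pd.DataFrame({
            "est_id": [f"E{i}" for i in range(5)],
            "transcript_id": ["NM_x1"] * 3 + ["NM_x2"] * 2,
            "library_id": ["L1"] * 5,
        })
        out = sd.collapse_to_genes(df, {"NM_x1": "G", "NM_x2": "G"})
        assert out.to_dict("records") == [
            {"gene_id": "G", "library_id": "L1", "count": 5}
        ]

    def test_empty_assignments_give_empty_counts(self):
        out = sd.collapse_to_genes(pd.DataFrame(
            columns=["est_id", "transcript_id", "library_id"]))
        assert out.empty

    def test_disjoint_genes_match_per_transcript_tally(self):
        rows = [("E1", "T1", "L1"), ("E2", "T1", "L1"), ("E3", "T2", "L2")]
        df = pd.DataFrame(rows, columns=["est_id", "transcript_id", "library_id"])
        out = sd.collapse_to_genes(df, {"T1": "G1", "T2": "G2"})
        # brute-force tally over the toy list
        expect = {}
        for _, tx, lib in rows:
            g = {"T1": "G1", "T2": "G2"}[tx]
            expect[(g, lib)] = expect.get((g, lib), 0) + 1
        got = {(r.gene_id, r.library_id): r["count"] for _, r in out.iterrows()}
        assert got == expect

    def test_unmapped_transcript_raises_with_offenders(self):
        df = pd.DataFrame({"est_id": ["E1"], "transcript_id": ["NM_zz"],
                           "library_id": ["L1"]})
        with pytest.raises(sd.ValidationError, match="NM_zz"):
            sd.collapse_to_genes(df, {"NM_x1": "G"})


class TestPslAndConservation:
    def test_psl_roundtrip_and_block_sums(self, tmp_path, small_corpus):
        path = tmp_path / "aln.psl"
        small_corpus.psl.to_csv(path, sep="\t", index=False, header=False)
        df = read_psl(path)
        assert len(df) == len(small_corpus.psl)
        hits = hits_from_psl(df)
        # multi-block rows: aligned span is the sum of block sizes
        two_block = df["blockCount"] == 2
        assert (hits.loc[two_block, "aligned_length"]
                == df.loc[two_block, "blockSizes"].str.rstrip(",")
                .str.split(",").map(lambda p: sum(map(int, p)))).all()

    def test_pslayout_header_skipped(self, tmp_path, small_corpus):
        path = tmp_path / "hdr.psl"
        body = small_corpus.psl.head(3).to_csv(sep="\t", index=False, header=False)
        path.write_text(
            "psLayout version 3\n\nmatch\tmis-\nmatch\tmatch\n"
            + "-" * 40 + "\n" + body
        )
        assert len(read_psl(path)) == 3

    def test_assignment_conservation(self, small_corpus):
        hits = hits_from_psl(small_corpus.psl)
        assigned, unassigned = assign_best_hits(hits)
        n_ests = hits["est_id"].nunique()
        assert len(assigned) + len(unassigned) == n_ests
        collapsed = sd.collapse_to_genes(
            attach_libraries(assigned, small_corpus.est_library),
            small_corpus.transcript_to_gene,
        )
        assert collapsed["count"].sum() == len(assigned)

    def test_decoy_alignments_never_assigned(self, small_corpus):
        """Sub-threshold rows (94.9% identity or 99 nt span) never count."""
        hits = hits_from_psl(small_corpus.psl)
        assigned, unassigned = assign_best_hits(hits)
        planted = set(small_corpus.est_library["est_id"]) - {
            e for e in small_corpus.est_library["est_id"] if ".U" in e
        }
        assert set(assigned["est_id"]) == planted
        assert all(".U" in e for e in unassigned)

    def test_gene_map_io(self, tmp_path, small_corpus):
        paths = sd.write_corpus(small_corpus, tmp_path)
        assert read_gene_map(paths["gene_map"]) == small_corpus.transcript_to_gene
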