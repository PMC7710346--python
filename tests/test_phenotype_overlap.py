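import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenoconcord import reference
from phenoconcord.errors import DomainError
from phenoconcord.phenotype_overlap import (
    OverlapCell,
    build_overlap_matrix,
    overlap_cell,
    recurrence_scores,
    round_half_up,
)
from phenoconcord.tables_io import DEGRecord, ExpressionDataset, PhenotypeSeedList


class TestOverlapCell:
    def test_published_facial_dysmorphisms_cell(self):
        cell = OverlapCell("patient", "facial_dysmorphisms", 212, 832, 5388)
        assert round_half_up(cell.pct_of_psg) == 25.5
        assert round_half_up(cell.pct_of_deg) == 3.9

    def test_disjoint_sets(self):
        psg = PhenotypeSeedList("x", frozenset({"A", "B"}))
        cell = overlap_cell({"C"}, psg, deg_size=1)
        assert (cell.n_overlap, cell.pct_of_psg, cell.pct_of_deg) == (0, 0.0, 0.0)

    def test_psg_subset_of_degs_is_100(self):
        psg = PhenotypeSeedList("x", frozenset({"A", "B"}))
        cell = overlap_cell({"A", "B", "C"}, psg, deg_size=3)
        assert cell.pct_of_psg == 100.0

    def test_empty_psg_rejected_unless_allowed(self):
        psg = PhenotypeSeedList("x", frozenset())
        with pytest.raises(DomainError):
            overlap_cell({"A"}, psg, deg_size=1)
        cell = overlap_cell({"A"}, psg, deg_size=1, allow_empty=True)
        assert not cell.applicable

    def test_half_up_display_rounding(self):
        # 62/181 = 34.2541... -> 34.3; half-up at the second decimal
        assert round_half_up(100 * 62 / 181) == 34.3
        assert round_half_up(27.25) == 27.3
        assert round_half_up(0.05, 1) == 0.1

    @given(
        st.integers(1, 500).flatmap(
            lambda s: st.tuples(st.just(s), st.integers(0, s), st.integers(1, 5000))
        )
    )
    def test_percentages_recomputable_from_counts(self, args):
        size, n, deg = args
        cell = OverlapCell("d", "p", n, size, max(deg, n))
        assert cell.pct_of_psg == 100.0 * cell.n_overlap / cell.psg_size
        assert 0.0 <= cell.pct_of_psg <= 100.0
        assert 0.0 <= cell.pct_of_deg <= 100.0


def _published_matrix():
    frame = reference.phenotype_overlap_counts()
    # re-express the printed counts as sets over disjoint placeholder symbols,
    # sized so every (overlap, psg_size) pair is exact
    deg, lists, next_id = set(), [], 0
    for row in frame.itertuples():
        inter = {f"X{next_id + i}" for i in range(row.n_overlap)}
        rest = {f"Y{next_id + i}" for i in range(row.psg_size - row.n_overlap)}
        next_id += row.psg_size
        deg |= inter
        lists.append(PhenotypeSeedList(row.phenotype, frozenset(inter | rest)))
    pad = {f"Z{i}" for i in range(reference.PATIENT_TOTAL_DEGS - len(deg))}
    return {"patient_blood": frozenset(deg | pad)}, lists


class TestOverlapMatrix:
    def test_published_per_cell_percentages(self):
        sets, lists = _published_matrix()
        matrix = build_overlap_matrix(sets, lists)
        frame = reference.phenotype_overlap_counts()
        printed = {
            "facial_dysmorphisms": (25.5, 3.9), "dd": (28.8, 4.5), "id": (26.5, 6.1),
            "asd": (23.4, 2.1), "speech_delay": (25.1, 2.3), "macrocephaly": (27.2, 1.9),
            "pes_planus": (34.3, 1.2), "hypotonia": (27.5, 4.8), "gi": (27.8, 3.8),
            "sleep": (25.6, 1.7), "anxiety": (27.2, 1.9), "dental": (28.5, 4.4),
        }
        for row in frame.itertuples():
            cell = matrix.cell("patient_blood", row.phenotype)
            assert cell.n_overlap == row.n_overlap
            want_psg, want_deg = printed[row.phenotype]
            assert round_half_up(cell.pct_of_psg) == want_psg
            assert round_half_up(cell.pct_of_deg) == want_deg

    def test_published_column_averages(self):
        sets, lists = _published_matrix()
        matrix = build_overlap_matrix(sets, lists)
        assert round_half_up(matrix.mean_pct_of_psg("patient_blood")) == 27.3
        assert round_half_up(matrix.mean_pct_of_deg("patient_blood")) == 3.2

    def test_single_cell_mean(self):
        lists = [PhenotypeSeedList("only", frozenset({"A", "B"}))]
        matrix = build_overlap_matrix({"d": frozenset({"A"})}, lists)
        assert matrix.mean_pct_of_psg("d") == matrix.cell("d", "only").pct_of_psg

    def test_union_counted_on_sets_not_summed(self):
        # three lists sharing one gene: union < sum of cells
        deg = frozenset({"A", "B", "C", "D", "E"})
        lists = [
            PhenotypeSeedList("p1", frozenset({"A", "B"})),
            PhenotypeSeedList("p2", frozenset({"A", "C"})),
            PhenotypeSeedList("p3", frozenset({"A", "D"})),
        ]
        matrix = build_overlap_matrix({"d": deg}, lists)
        cell_sum = sum(matrix.cell("d", p.phenotype).n_overlap for p in lists)
        assert matrix.union_counts["d"] == 4 < cell_sum == 6

    def test_union_bound_equality_iff_disjoint(self):
        deg = frozenset({"A", "B"})
        disjoint = [
            PhenotypeSeedList("p1", frozenset({"A"})),
            PhenotypeSeedList("p2", frozenset({"B"})),
        ]
        matrix = build_overlap_matrix({"d": deg}, disjoint)
        assert matrix.union_counts["d"] == sum(
            matrix.cell("d", p.phenotype).n_overlap for p in disjoint
        )

    def test_phenotype_order_invariance(self):
        sets, lists = _published_matrix()
        forward = build_overlap_matrix(sets, lists)
        backward = build_overlap_matrix(sets, lists[::-1])
        assert forward.mean_pct_of_psg("patient_blood") == pytest.approx(
            backward.mean_pct_of_psg("patient_blood")
        )
        assert forward.union_counts == backward.union_counts

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            build_overlap_matrix({}, [])


class TestRecurrence:
    @pytest.fixture
    def concordant_inputs(self):
        sets, psg_lists = reference.concordant_gene_memberships()
        genes = sets["patient_blood"]
        records = [
            DEGRecord(gene=g, log2fc=-0.35 if g == "TCF4" else 0.5, p_value=0.001, q_value=0.01)
            for g in genes
        ]
        return ExpressionDataset.from_records("patient_blood", records), genes, psg_lists

    def test_tcf4_in_nine_phenotypes(self, concordant_inputs):
        ds, genes, lists = concordant_inputs
        recs = {r.gene: r for r in recurrence_scores(genes, ds, lists, min_count=0)}
        assert recs["TCF4"].n_phenotypes == 9
        assert recs["NFIA"].n_phenotypes == 3
        assert recs["RGMB"].n_phenotypes == 1

    def test_absent_gene_scores_zero_and_filtered(self, concordant_inputs):
        ds, genes, lists = concordant_inputs
        all_recs = recurrence_scores(genes, ds, lists, min_count=0)
        assert {r.gene for r in all_recs if r.n_phenotypes == 0} == {
            "CELF2", "EML6", "FBXL19", "PODXL", "RIMS3"
        }
        assert all(
            r.n_phenotypes >= 1 for r in recurrence_scores(genes, ds, lists, min_count=1)
        )

    def test_sorted_by_recurrence_then_lfc(self, concordant_inputs):
        ds, genes, lists = concordant_inputs
        recs = recurrence_scores(genes, ds, lists, min_count=1)
        keys = [(-r.n_phenotypes, -r.log2fc) for r in recs]
        assert keys == sorted(keys)


def test_enrichment_recovery_binomial():
    """With every seed gene either planted in the DEG set (probability e) or
    not, the mean pct_of_psg across replicates converges to 100*e."""
    rng = np.random.default_rng(11)
    e, size, reps = 0.3, 200, 100
    universe = [f"G{i}" for i in range(5000)]
    pcts = []
    for _ in range(reps):
        member = rng.choice(universe, size=size, replace=False)
        planted = member[rng.uniform(size=size) < e]
        lists = [PhenotypeSeedList("p", frozenset(member))]
        matrix = build_overlap_matrix({"d": frozenset(planted)}, lists)
        pcts.append(matrix.cell("d", "p").pct_of_psg)
    se = 100 * np.sqrt(e * (1 - e) / size) / np.sqrt(reps)
    assert abs(np.mean(pcts) - 100 * e) < 4 * se
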