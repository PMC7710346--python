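import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def generic_deg_file(tmp_path):
    """Three-row generic DEG TSV (the fold-change extremes of the patient table)."""
    path = tmp_path / "three_rows.tsv"
    path.write_text(
        "gene\tlog2fc\tp_value\tq_value\n"
        "THBS1\t-4.04863\t5.00E-05\t0.000316967\n"
        "GRIK4\t3.95099\t0.0002\t0.00107189\n"
        "VSIG2\t3.55333\t0.0196\t0.0477048\n"
    )
    return path


@pytest.fixture
def cuffdiff_file(tmp_path):
    """Five-row gene_exp.diff, two rows not testable (status NOTEST)."""
    header = (
        "test_id\tgene_id\tgene\tlocus\tsample_1\tsample_2\tstatus\tvalue_1\t"
        "value_2\tlog2(fold_change)\ttest_stat\tp_value\tq_value\tsignificant\n"
    )
    rows = [
        "g1\tg1\tTHBS1\tchr15:1-2\tctrl\tcase\tOK\t10\t1\t-3.32\t-5.0\t5e-05\t0.00032\tyes",
        "g2\tg2\tGRIK4\tchr11:1-2\tctrl\tcase\tOK\t1\t15\t3.9\t4.0\t0.0002\t0.00107\tyes",
        "g3\tg3\tLOWEXP\tchr1:1-2\tctrl\tcase\tNOTEST\t0\t0\t0\t0\t1\t1\tno",
        "g4\tg4\tZEROCASE\tchr2:1-2\tctrl\tcase\tOK\t5\t0\t-inf\t0\t0.001\t0.004\tyes",
        "g5\tg5\tHIDATA\tchr3:1-2\tctrl\tcase\tNOTEST\t9999\t9999\t0\t0\t1\t1\tno",
    ]
    path = tmp_path / "gene_exp.diff"
    path.write_text(header + "\n".join(rows) + "\n")
    return path
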