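"""Packaged reference values from the CHD8-haploinsufficiency case study.

These small tables hold the published summary numbers of the blood-versus-
sibling patient transcriptome and the five public cellular-model datasets
(neural progenitors, neurons, cerebral organoids): the 23 most fold-changed
patient DEGs, the twelve phenotype seed-list overlap counts, the six
per-study DEG totals, the sixteen highly recurrent seed-gene DEGs, and the
cross-study membership of the eight genes differentially expressed in at
least five of the six datasets.  The raw patient data are controlled-access;
these printed summaries are the reproducible anchor the pipeline is checked
against.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tables_io import ExpressionDataset, PhenotypeSeedList, read_deg_table

#: total significant patient DEGs at q < 0.05 (blood vs. matched sibling)
PATIENT_TOTAL_DEGS = 5388

#: fixed study order used throughout the concordance tables
STUDY_ORDER = (
    "patient_blood",
    "wang_organoid",
    "wang_neurons",
    "wang_npc",
    "wilkinson_npc",
    "sugathan_npc",
)


def _path(name: str):
    return resources.files("phenoconcord.data") / name


def patient_top_degs() -> ExpressionDataset:
    """The 23 patient DEGs with |log2fc| >= 3, as a dataset."""
    with resources.as_file(_path("patient_top_degs.tsv")) as p:
        return read_deg_table(p, dialect="generic", name="patient_blood_top",
                              model_type="patient blood (PBMC)")


def phenotype_overlap_counts() -> pd.DataFrame:
    """Per-phenotype (overlap, seed-list size) counts for the patient dataset."""
    with resources.as_file(_path("phenotype_overlap_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def deg_counts() -> dict[str, int]:
    """Published per-study DEG totals at the uniform q < 0.05 threshold."""
    with resources.as_file(_path("deg_counts.tsv")) as p:
        frame = pd.read_csv(p, sep="\t")
    return dict(zip(frame["model"], frame["n_degs"].astype(int)))


def recurrent_degs() -> pd.DataFrame:
    """The 16 patient DEGs that are seed genes in >= 9 of the 12 phenotypes."""
    with resources.as_file(_path("recurrent_degs.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def concordant_gene_memberships() -> tuple[dict[str, frozenset[str]], list[PhenotypeSeedList]]:
    """Cross-study DEG membership of the >=5-of-6 concordant genes.

    Returns per-study gene sets (restricted to those eight genes) in
    :data:`STUDY_ORDER`, plus the phenotype seed lists *restricted to the
    same genes* — enough to reproduce the published core intersections,
    leave-one-out cores and the seed/non-seed partition.
    """
    with resources.as_file(_path("concordant_gene_memberships.tsv")) as p:
        frame = pd.read_csv(p, sep="\t", keep_default_na=False)
    sets: dict[str, frozenset[str]] = {
        study: frozenset(frame.loc[frame[study] == 1, "gene"]) for study in STUDY_ORDER
    }
    by_phenotype: dict[str, set[str]] = {}
    for _, row in frame.iterrows():
        for phenotype in str(row["phenotypes"]).split(";"):
            if phenotype:
                by_phenotype.setdefault(phenotype, set()).add(row["gene"])
    psg_lists = [
        PhenotypeSeedList(phenotype=k, genes=frozenset(v))
        for k, v in sorted(by_phenotype.items())
    ]
    return sets, psg_lists
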