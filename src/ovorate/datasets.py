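"""Published summary tables shipped with the package.

These are the printed per-gene branch dN/dS tokens, PGLS coefficients and
predictions, enrichment counts, species ovariole numbers and genome-wide
summary figures for the five-species melanogaster subgroup analysis.
They are inputs (data), not outputs: the package recomputes predictions
and test statistics *from* them; it does not re-estimate them (the
underlying genome alignments and ML branch lengths are not published).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ratetable import BranchRateRecord, OmegaCode

SPECIES = ["Dsim", "Dsec", "Dmel", "Dyak", "Dere"]


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files("ovorate.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", **kw)


def branch_omega_published() -> pd.DataFrame:
    """Per-gene branch omega tokens (numbers, '>1', '-') for the 42
    candidate ovariole-related genes, plus M0 omega and tau where printed."""
    return _read("branch_omega_published.tsv", dtype={sp: str for sp in SPECIES})


def pgls_published() -> pd.DataFrame:
    """Published PGLS coefficients and per-species predictions for the 17
    genes with a significant phenotype ~ omega relationship."""
    return _read("pgls_published.tsv")


def ovariole_numbers() -> pd.Series:
    df = _read("ovariole_numbers.tsv")
    return df.set_index("species")["ovariole_number"]


def enrichment_published() -> pd.DataFrame:
    """Published enrichment comparisons: counts, genome proportions and the
    printed one-tailed chi-square P values."""
    return _read("enrichment_published.tsv")


def genome_summary() -> pd.Series:
    df = _read("genome_summary.tsv")
    return df.set_index("quantity")["value"]


def gene_branch_records(gene_id: str) -> list[BranchRateRecord]:
    """Published per-species branch records for one gene (dN/dS tokens
    only; dN and dS themselves are not printed and enter as NaN)."""
    table = branch_omega_published().set_index("gene_id")
    if gene_id not in table.index:
        raise KeyError(f"gene {gene_id!r} not in the published table")
    row = table.loc[gene_id]
    records = []
    for sp in SPECIES:
        token = str(row[sp]).strip()
        if token == ">1":
            records.append(
                BranchRateRecord(gene_id, sp, float("nan"), float("nan"), OmegaCode.GT1)
            )
        elif token == "-":
            records.append(
                BranchRateRecord(gene_id, sp, float("nan"), float("nan"), OmegaCode.LOWDIV)
            )
        else:
            records.append(
                BranchRateRecord(
                    gene_id, sp, float("nan"), float("nan"), OmegaCode.VALUE, float(token)
                )
            )
    return records
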