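import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from homeopart.bias import call_silencing
from homeopart.model import BiasCategory, TISSUE_STAGE

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


def make_calls(assignments: dict) -> pd.DataFrame:
    """Build a classified calls frame from category assignments.

    ``assignments`` maps (gene_id, individual_id, group) to a
    {tissue: BiasCategory} dict; silencing/expression flags are derived
    exactly as classify_table would.
    """
    rows = []
    for (gene, ind, group), tissues in assignments.items():
        for tissue, cat in tissues.items():
            cat = BiasCategory(cat)
            sil_n, sil_9 = call_silencing(cat)
            no_expr = cat is BiasCategory.NO_EXPRESSION
            rows.append(
                {
                    "gene_id": gene,
                    "individual_id": ind,
                    "group": group,
                    "tissue": tissue,
                    "stage": TISSUE_STAGE[tissue],
                    "category": cat.value,
                    "silenced_n": sil_n,
                    "silenced_9": sil_9,
                    "expressed_n": not sil_n and not no_expr,
                    "expressed_9": not sil_9 and not no_expr,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def tiny_assay_tsv(tmp_path):
    """A small valid raw assay table on disk."""
    path = tmp_path / "assays.tsv"
    lines = ["gene_id\tpathway\tindividual_id\tgroup\ttissue\tsignal_N\tsignal_9"]
    for gene in ("HK01", "CP02"):
        for ind, group in (("MIX_1", "MIX"), ("F1_1", "F1")):
            for tissue in ("L1", "R1", "L2", "R2", "F", "S"):
                lines.append(f"{gene}\tHK\t{ind}\t{group}\t{tissue}\t120\t80")
    path.write_text("\n".join(lines) + "\n")
    return path
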