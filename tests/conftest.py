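import pandas as pd
import pytest

from nematax import Lineage, SupportTree, TaxonMap


def make_lineage(family, order="OrdA", genus=None, species=None, phylum="Nematoda"):
    pairs = [("phylum", phylum), ("order", order), ("family", family)]
    if genus:
        pairs.append(("genus", genus))
    if species:
        pairs.append(("species", species))
    return Lineage.from_pairs(pairs)


@pytest.fixture
def two_family_taxa():
    """A1,A2 -> FamA; B1,B2 -> FamB; plus one non-voucher label."""
    return TaxonMap(
        {
            "A1": make_lineage("FamA", genus="GenA1"),
            "A2": make_lineage("FamA", genus="GenA2"),
            "B1": make_lineage("FamB", genus="GenB1"),
            "B2": make_lineage("FamB", genus="GenB2"),
            "uncultured eukaryote clone X": make_lineage("FamA"),
        }
    )


@pytest.fixture
def two_family_tree():
    return SupportTree.from_newick("((A1:1,A2:1)95:1,(B1:1,B2:1)99:1);")


@pytest.fixture
def interleaved_tree():
    return SupportTree.from_newick("((A1:1,B1:1)90:1,(A2:1,B2:1)90:1);")


def hits_frame_to_table(rows):
    """rows of (query, subject, identity, coverage, bitscore) -> HitTable"""
    from nematax import HitRecord, HitTable

    return HitTable([HitRecord(*r) for r in rows])


@pytest.fixture
def morpho_frame():
    return pd.DataFrame(
        {
            "family": ["FamA", "FamB"],
            "sample": ["S1", "S1"],
            "morphospecies_count": [3, 1],
        }
    )
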