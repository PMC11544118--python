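"""Small worked-example inputs.

The checkpoint-ligand list pair here is SYNTHETIC: it reproduces only the
set cardinalities of the published screen (29 lncRNAs tracking PD-L1, 85
tracking PD-L2, 22 shared) with made-up identifiers, because the original
supplementary identifier lists are not redistributable here.  It exists
to exercise the intersection step on a realistically shaped input.
"""

from __future__ import annotations

__all__ = ["synthetic_ligand_correlated_lists"]


def synthetic_ligand_correlated_lists() -> tuple:
    """(PD-L1-correlated, PD-L2-correlated) synthetic lncRNA id lists.

    29 and 85 ids respectively, sharing exactly 22; ids are versioned in
    the first list and bare in the second to exercise id normalisation.
    """
    shared = [f"ENSG1001{i:04d}" for i in range(1, 23)]
    pd_l1_only = [f"ENSG2001{i:04d}" for i in range(1, 8)]
    pd_l2_only = [f"ENSG3001{i:04d}" for i in range(1, 64)]
    pd_l1 = [f"{g}.{(i % 5) + 1}" for i, g in enumerate(shared + pd_l1_only)]
    pd_l2 = shared + pd_l2_only
    assert len(pd_l1) == 29 and len(pd_l2) == 85
    return pd_l1, pd_l2
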