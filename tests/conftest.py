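"""Shared fixtures: tiny hand-built datasets and on-disk input files."""

import numpy as np
import pytest

from regiospec.io_core import ExpressionDataset, GeneAnnotation


def make_dataset(values, genes=None, regions=None, timepoints=None,
                 species="test"):
    """Build an ExpressionDataset from a nested array (gene x region x tp)."""
    values = np.asarray(values, dtype=float)
    g, r, t = values.shape
    return ExpressionDataset(
        genes or [f"g{i}" for i in range(g)],
        regions or [f"R{j}" for j in range(r)],
        timepoints or [f"t{k}" for k in range(t)],
        values, species)


@pytest.fixture
def toy_dataset():
    """3 genes x 3 regions x 2 timepoints with exact hand-checkable values."""
    vals = np.zeros((3, 3, 2))
    # t0: R1=(1,2,4), R2=(1,3,5), R3=(2,2,2) across the 3 genes
    vals[:, 0, 0] = [1, 2, 4]
    vals[:, 1, 0] = [1, 3, 5]
    vals[:, 2, 0] = [2, 2, 2]
    # t1: R1=(1,2,3), R2=(3,2,1) perfectly anticorrelated, R3=(1,2,3)
    vals[:, 0, 1] = [1, 2, 3]
    vals[:, 1, 1] = [3, 2, 1]
    vals[:, 2, 1] = [1, 2, 3]
    return make_dataset(vals, regions=["R1", "R2", "R3"])


@pytest.fixture
def flat_annotation():
    """Flat GO annotation: parent P with children A, B; gene sets attached."""
    parents = {"GO:P": set(), "GO:A": {"GO:P"}, "GO:B": {"GO:P"},
               "GO:C": set()}
    g2t = {f"g{i}": {"GO:A"} for i in range(5)}
    g2t.update({f"h{i}": {"GO:B"} for i in range(5)})
    return GeneAnnotation(g2t, parents).propagate()


@pytest.fixture
def obo_file(tmp_path):
    text = """format-version: 1.2

[Term]
id: GO:0000001
name: root process

[Term]
id: GO:0000002
name: child process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: grandchild process
is_a: GO:0000002 ! child process
"""
    p = tmp_path / "mini.obo"
    p.write_text(text)
    return p
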