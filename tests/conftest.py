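import itertools

import numpy as np
import pytest

from dielscan.io import Alignment, SampleMetadata, SampleRow, SequenceRecord
from dielscan.phylo import discrete_gamma_rates, _compress_patterns


def make_alignment(rows: dict[str, str]) -> Alignment:
    return Alignment(tuple(SequenceRecord(k, v) for k, v in rows.items()))


def make_metadata(spec: dict[str, tuple[str, str]]) -> SampleMetadata:
    """spec: id -> (group, behavior)."""
    return SampleMetadata(
        {
            sid: SampleRow(species=sid, group=g, behavior=b, in_primate_tests=(g != "outgroup"))
            for sid, (g, b) in spec.items()
        }
    )


@pytest.fixture
def table1_metadata():
    from dielscan.simulate import table1_fixture

    meta, _ = table1_fixture()
    return meta


@pytest.fixture
def table1_tree():
    from dielscan.simulate import table1_fixture
    from dielscan.phylo import Tree

    _, newick = table1_fixture()
    return Tree.from_newick(newick)


def brute_force_loglik(tree, alignment, params) -> float:
    """Independent likelihood oracle: explicit summation over all internal-node
    state assignments, per site and per gamma category, with transition
    matrices from scipy's matrix exponential rather than the package's
    eigendecomposition path."""
    from scipy.linalg import expm

    from dielscan.phylo import hky_rate_matrix

    ids, patterns, counts = _compress_patterns(alignment)
    pi = np.asarray(params.base_freqs, dtype=float)
    Q = hky_rate_matrix(params.kappa, pi)
    rates = discrete_gamma_rates(params.alpha, params.n_categories)
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_tip]
    total = 0.0
    for pat, cnt in zip(patterns.T, counts):
        site_lik = 0.0
        for r in rates:
            pmats = {
                id(n): expm(Q * (n.length or 0.0) * r)
                for n in nodes
                if n.parent is not None
            }
            acc = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = {id(n): a for n, a in zip(internals, assign)}
                pr = pi[amap[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    state = pat[ids.index(n.name)] if n.is_tip else amap[id(n)]
                    pr *= pmats[id(n)][amap[id(n.parent)], state]
                acc += pr
            site_lik += acc / len(rates)
        total += cnt * np.log(site_lik)
    return float(total)
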