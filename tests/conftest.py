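"""Shared fixtures: a synthetic template context and trimming spec.

The vector context below is a synthetic stand-in assembled from the public
U6-promoter / sgRNA-scaffold sequence family plus an I-SceI-bearing
placeholder; it reproduces the structural rules (arm homology sources, a
placeholder whose destruction the clean-up digest requires) without being
any specific plasmid's verbatim sequence.
"""

import pytest

from threecs import TemplateContext, TrimSpec

U6_TAIL = "CTTGTGGAAAGGACGAAACACCG"
SCAFFOLD_HEAD = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCG"
# 20-nt placeholder protospacer containing the I-SceI recognition site.
PLACEHOLDER = "GTAGGGATAACAGGGTAATC"
ADAPTER = SCAFFOLD_HEAD[:23]


@pytest.fixture
def ctx() -> TemplateContext:
    return TemplateContext(U6_TAIL, SCAFFOLD_HEAD, PLACEHOLDER)


@pytest.fixture
def trim_spec() -> TrimSpec:
    return TrimSpec(ADAPTER, keep_last=20)
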