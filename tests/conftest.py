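"""Shared fixtures: the TRAF2/CD40 worked example and tiny inventories."""

import pytest

from bioevents.graph import (
    CANDIDATE_ANCHOR,
    PROTEIN,
    Token,
    TypeInventory,
    ge_inventory,
)
from bioevents.standoff import Span, read_document

FIG_TEXT = "the phosphorylation of TRAF2 inhibits binding to the CD40 cytoplasmic domain"

FIG_A1 = """\
T1\tProtein 23 28\tTRAF2
T2\tProtein 53 57\tCD40
"""

FIG_A2 = """\
T3\tPhosphorylation 4 19\tphosphorylation
T4\tRegulation 29 37\tinhibits
T5\tBinding 38 45\tbinding
E1\tPhosphorylation:T3 Theme:T1
E2\tRegulation:T4 Theme:E3 Cause:E1
E3\tBinding:T5 Theme:T1 Theme2:T2
"""


@pytest.fixture
def fig_doc():
    """The canonical three-event example: a Phosphorylation of TRAF2 is the
    CAUSE of a Regulation whose THEME is a TRAF2-CD40 Binding."""
    return read_document(FIG_TEXT, FIG_A1, FIG_A2, doc_id="fig")


@pytest.fixture
def fig_tokens():
    """Head tokens of the example's participants, in sentence order."""
    return [
        Token(0, "phosphorylation", Span(4, 19), CANDIDATE_ANCHOR),
        Token(1, "TRAF2", Span(23, 28), PROTEIN, ref_id="T1"),
        Token(2, "inhibits", Span(29, 37), CANDIDATE_ANCHOR),
        Token(3, "binding", Span(38, 45), CANDIDATE_ANCHOR),
        Token(4, "CD40", Span(53, 57), PROTEIN, ref_id="T2"),
    ]


@pytest.fixture
def inv():
    return ge_inventory()


@pytest.fixture
def tiny_inv():
    """Three-type inventory used for exhaustive-enumeration oracles."""
    return TypeInventory(
        simple_types=frozenset({"Phosphorylation"}),
        binding_types=frozenset({"Binding"}),
        regulation_types=frozenset({"Regulation"}),
        cause_licensed_types=frozenset({"Regulation"}),
    )
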