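"""Frozen expected outcomes of the mutant screen.

Each entry pairs a perturbation with the checks its published model-outcome
description translates into:

* ``no_damage`` — fate string of the unique stable state at (SSB,DSB)=(0,0)
  ("proliferation", "cycle_arrest", ...; joined with "+" when several
  outputs are active);
* ``no_damage_bistable`` — sorted fate strings when (0,0) is multistable;
* ``annotations`` — change annotations that must be present;
* ``annotations_absent`` — annotations that must NOT be present (e.g. a
  row reporting only "loss of senescence" implies apoptosis is retained);
* ``apoptosis_all_damage`` — apoptosis occurs at every damage condition;
* ``apoptosis_everywhere`` — apoptosis at all nine conditions;
* ``damage_similar_wt`` — fates identical to wild type on the eight damage
  conditions (rows whose comparison protocol includes DNA damage are
  compared on damage conditions only).

Every expectation was derived by hand-propagating the logical rules before
being frozen here; the screen must reproduce all of them.
"""

from logicfate import Perturbation, gain_of_function, loss_of_function


def lof(*names):
    return loss_of_function(*names)


def gof(name, lo, hi=None):
    return gain_of_function(name, lo, hi)


# (perturbation, expected-checks)
SCREEN_EXPECTATIONS = [
    # --- loss of function ---------------------------------------------------
    (lof("p38MAPK"), {
        "annotations": {"loss of senescence", "loss of apoptosis"},
    }),
    (lof("CHEK2"), {
        "annotations": {"loss of senescence"},
        "annotations_absent": {"loss of apoptosis"},
    }),
    (lof("ATM"), {
        "annotations": {"loss of senescence", "loss of apoptosis"},
    }),
    (lof("CHEK1"), {
        "no_damage": "proliferation",
        "annotations": {"loss of senescence"},
        "annotations_absent": {"loss of apoptosis"},
    }),
    (lof("p14ARF"), {
        "no_damage": "proliferation",
        "annotations": {"senescence enhanced", "loss of apoptosis"},
    }),
    (lof("Mdm2"), {
        "no_damage": "proliferation",
        "apoptosis_all_damage": True,
    }),
    (lof("p16INK4a"), {
        "no_damage": "proliferation",
        "annotations": {"loss of senescence"},
        "annotations_absent": {"loss of apoptosis"},
    }),
    (lof("p21"), {
        "no_damage": "proliferation",
        "annotations": {"loss of senescence"},
        "annotations_absent": {"loss of apoptosis"},
    }),
    (lof("p53"), {
        "no_damage": "proliferation",
        "annotations": {"loss of senescence", "loss of apoptosis"},
    }),
    (lof("ATR"), {
        "no_damage": "proliferation",
        "annotations": {"senescence enhanced", "loss of apoptosis"},
    }),
    (lof("CDC25A"), {
        "no_damage": "cycle_arrest",
        "annotations": {"loss of proliferation", "senescence enhanced"},
    }),
    (lof("RB1"), {
        "no_damage": "proliferation",
        "apoptosis_all_damage": True,
    }),
    (lof("E2F"), {
        "no_damage": "cycle_arrest",
        "annotations": {"loss of proliferation"},
        "damage_similar_wt": True,
    }),
    (lof("p53", "Mdm2"), {
        "no_damage": "proliferation",
        "annotations": {"loss of senescence", "loss of apoptosis"},
    }),
    # --- gain of function ----------------------------------------------------
    (gof("CHEK2", 1), {
        "annotations": {"senescence enhanced"},
    }),
    (gof("Mdm2", 1), {
        "annotations": {"senescence enhanced", "loss of apoptosis"},
    }),
    (gof("p21", 1), {
        "damage_similar_wt": True,
    }),
    (gof("p38MAPK", 1), {
        "no_damage": "cycle_arrest",
        "annotations": {"loss of proliferation", "senescence enhanced",
                        "loss of apoptosis"},
    }),
    (gof("p38MAPK", 2), {
        "no_damage": "cycle_arrest",
        "annotations": {"loss of proliferation", "senescence enhanced",
                        "loss of apoptosis"},
    }),
    (gof("p38MAPK", 3), {
        "no_damage": "apoptosis+cycle_arrest",
        "apoptosis_everywhere": True,
    }),
    (gof("CHEK1", 1), {
        "no_damage": "cycle_arrest",
        "damage_similar_wt": True,
    }),
    (gof("p14ARF", 1), {
        "no_damage": "proliferation",
        "apoptosis_all_damage": True,
    }),
    (gof("p16INK4a", 1, 2), {
        "no_damage_bistable": ["cycle_arrest", "proliferation"],
        "damage_similar_wt": True,
    }),
    (gof("p16INK4a", 2), {
        "annotations": {"senescence enhanced"},
    }),
    (gof("p53", 1), {
        "no_damage": "cycle_arrest",
        "annotations": {"loss of proliferation", "senescence enhanced",
                        "loss of apoptosis"},
    }),
    (gof("p53", 2), {
        "apoptosis_everywhere": True,
    }),
    (gof("ATM", 1), {
        "no_damage": "cycle_arrest",
        "annotations": {"loss of senescence", "loss of apoptosis"},
    }),
    (gof("ATM", 2), {
        "no_damage": "cycle_arrest+senescence",
        "annotations": {"senescence enhanced"},
    }),
    (gof("ATR", 1), {
        "no_damage": "cycle_arrest",
        "annotations": {"loss of proliferation", "senescence enhanced",
                        "loss of apoptosis"},
    }),
    (gof("ATR", 2), {
        "no_damage": "cycle_arrest",
        "annotations": {"loss of senescence", "apoptosis enhanced"},
    }),
    (gof("CDC25A", 2), {
        "no_damage": "proliferation",
        "annotations": {"loss of senescence"},
    }),
    (gof("RB1", 1), {
        "no_damage": "cycle_arrest",
        "annotations": {"loss of proliferation"},
        "damage_similar_wt": True,
    }),
    (gof("E2F", 1), {
        "no_damage": "proliferation",
        "apoptosis_all_damage": True,
    }),
]


def check_screen_result(result, wt_fates, expected):
    """Assert one screen row against its frozen expectation."""
    no_damage = result.fates[(0, 0)]
    if "no_damage" in expected:
        assert len(no_damage) == 1, f"{result.label}: (0,0) not monostable"
        assert "+".join(sorted(no_damage[0])) == expected["no_damage"], result.label
    if "no_damage_bistable" in expected:
        got = sorted("+".join(sorted(f)) for f in no_damage)
        assert got == expected["no_damage_bistable"], result.label
    for ann in expected.get("annotations", ()):
        assert ann in result.annotations, (
            f"{result.label}: missing annotation {ann!r} in {sorted(result.annotations)}"
        )
    for ann in expected.get("annotations_absent", ()):
        assert ann not in result.annotations, (
            f"{result.label}: unexpected annotation {ann!r}"
        )
    damage_conditions = [c for c in result.fates if c != (0, 0)]
    if expected.get("apoptosis_all_damage"):
        for cond in damage_conditions:
            assert result.fate_occurs("apoptosis", cond), (
                f"{result.label}: no apoptosis at {cond}"
            )
    if expected.get("apoptosis_everywhere"):
        for cond in result.fates:
            assert result.fate_occurs("apoptosis", cond), (
                f"{result.label}: no apoptosis at {cond}"
            )
    if expected.get("damage_similar_wt"):
        for cond in damage_conditions:
            assert set(result.fates[cond]) == set(wt_fates[cond]), (
                f"{result.label}: fates at {cond} differ from wild type"
            )
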