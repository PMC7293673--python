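"""Built-in registry of the pilot-plant assay conditions.

The design of experiments covers three targets and their associated
blank assays, all at pH 2.8 +/- 0.2 and 28 +/- 2 C with a 300-420 nm
lamp (irradiated volume 1.5 L when lit):

* four reagent-only blanks (BLANK_1-4) used to estimate the core
  constants;
* a 3x3 factorial over [H2O2]0 x [Fe2+]0 for paracetamol
  (EXP1-18_PCT, dark then irradiated) at [PCT]0 = 0.26 mmol/L, plus
  five standard blanks with the target present (BLANK_5-9);
* a 1x3 oxidant factorial for sulfaquinoxaline sodium salt
  (EXP1-6_SQX) at [SQX]0 = 0.08 mmol/L with five blanks (BLANK_10-14);
* five formic-acid assays (EXP1-5_FA) at [FA]0 = 0.87 mmol/L.

All runs last 120 min in batch mode with 12 L/min recirculation.
"""

from __future__ import annotations

from .reactor import ExperimentSpec

__all__ = [
    "EXPERIMENTS",
    "TRAINING_SETS",
    "CORE_BLANKS",
    "get_experiment",
    "list_experiments",
    "doe_experiments",
]


def _exp(
    exp_id: str,
    compound: str | None,
    target0: float,
    h2o2_0: float,
    fe2_0: float,
    irradiated: bool,
) -> ExperimentSpec:
    return ExperimentSpec(
        id=exp_id,
        compound=compound,
        target0=target0,
        fe2_0=fe2_0,
        h2o2_0=h2o2_0,
        irradiated=irradiated,
    )


def _build_registry() -> dict[str, ExperimentSpec]:
    reg: dict[str, ExperimentSpec] = {}

    # Reagent-only blanks (no target anywhere).
    for exp_id, h2o2, fe2, irr in [
        ("BLANK_1", 11.12, 0.00, False),
        ("BLANK_2", 11.12, 0.00, True),
        ("BLANK_3", 11.12, 0.18, False),
        ("BLANK_4", 11.12, 0.18, True),
    ]:
        reg[exp_id] = _exp(exp_id, None, 0.0, h2o2, fe2, irr)

    # Standard blanks with PCT present (oxidant-only / catalyst-only /
    # photolysis checks).
    for exp_id, h2o2, fe2, irr in [
        ("BLANK_5", 11.12, 0.00, False),
        ("BLANK_6", 0.00, 0.18, False),
        ("BLANK_7", 11.12, 0.00, True),
        ("BLANK_8", 0.00, 0.18, True),
        ("BLANK_9", 0.00, 0.00, True),
    ]:
        reg[exp_id] = _exp(exp_id, "PCT", 0.26, h2o2, fe2, irr)

    # PCT factorial: oxidant x catalyst, dark (1-9) then irradiated (10-18).
    h2o2_levels = [2.78, 5.56, 11.12]
    fe2_levels = [0.09, 0.13, 0.18]
    n = 1
    for irr in (False, True):
        for h2o2 in h2o2_levels:
            for fe2 in fe2_levels:
                exp_id = f"EXP{n}_PCT"
                reg[exp_id] = _exp(exp_id, "PCT", 0.26, h2o2, fe2, irr)
                n += 1

    # SQX blanks (target present) and oxidant factorial at fixed iron.
    for exp_id, h2o2, fe2, irr in [
        ("BLANK_10", 6.94, 0.00, False),
        ("BLANK_11", 0.00, 0.18, False),
        ("BLANK_12", 6.94, 0.00, True),
        ("BLANK_13", 0.00, 0.18, True),
        ("BLANK_14", 0.00, 0.00, True),
    ]:
        reg[exp_id] = _exp(exp_id, "SQX", 0.08, h2o2, fe2, irr)
    n = 1
    for irr in (False, True):
        for h2o2 in [3.47, 5.24, 6.94]:
            exp_id = f"EXP{n}_SQX"
            reg[exp_id] = _exp(exp_id, "SQX", 0.08, h2o2, 0.18, irr)
            n += 1

    # FA assays.
    for exp_id, h2o2, fe2, irr in [
        ("EXP1_FA", 0.88, 0.09, False),
        ("EXP2_FA", 1.76, 0.09, False),
        ("EXP3_FA", 0.88, 0.09, True),
        ("EXP4_FA", 1.76, 0.09, True),
        ("EXP5_FA", 4.41, 0.18, True),
    ]:
        reg[exp_id] = _exp(exp_id, "FA", 0.87, h2o2, fe2, irr)

    return reg


EXPERIMENTS: dict[str, ExperimentSpec] = _build_registry()

#: Blanks used to estimate the core constants (iron + oxidant, no target).
CORE_BLANKS = ("BLANK_3", "BLANK_4")

#: Experiment IDs used for parameter identification per compound.
TRAINING_SETS: dict[str, tuple[str, ...]] = {
    "PCT": (
        "EXP1_PCT",
        "EXP4_PCT",
        "EXP5_PCT",
        "EXP9_PCT",
        "EXP10_PCT",
        "EXP13_PCT",
        "EXP14_PCT",
        "EXP18_PCT",
    ),
    "SQX": tuple(f"EXP{i}_SQX" for i in range(1, 7)),
    "FA": tuple(f"EXP{i}_FA" for i in range(1, 6)),
}


def get_experiment(exp_id: str) -> ExperimentSpec:
    try:
        return EXPERIMENTS[exp_id.upper()]
    except KeyError:
        raise KeyError(
            f"unknown experiment {exp_id!r}; see list_experiments()"
        ) from None


def list_experiments(compound: str | None = None) -> list[str]:
    """All experiment IDs, optionally restricted to one compound."""
    if compound is None:
        return list(EXPERIMENTS)
    compound = compound.upper()
    return [k for k, v in EXPERIMENTS.items() if v.compound == compound]


def doe_experiments(compound: str) -> list[str]:
    """The factorial rows plus associated blanks for one compound's study."""
    return list_experiments(compound)
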