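"""Cause-of-death and age-class strata used throughout the package."""

CAUSES = ("cvd", "resp", "other")
AGES = ("15_64", "65_74", "75p")

#: column names of the 3x3 stratified daily death counts, row-major by cause
STRATA = tuple((c, a) for c in CAUSES for a in AGES)


def death_column(cause: str, age: str) -> str:
    """Canonical CSV column name for one cause x age stratum."""
    if cause not in CAUSES:
        raise ValueError(f"unknown cause {cause!r}; expected one of {CAUSES}")
    if age not in AGES:
        raise ValueError(f"unknown age class {age!r}; expected one of {AGES}")
    return f"deaths_{cause}_{age}"


DEATH_COLUMNS = tuple(death_column(c, a) for c, a in STRATA)


def select_death_columns(cause: str | None = None, age: str | None = None) -> list[str]:
    """Death-count columns matching a (possibly marginal) stratum selector.

    ``cause=None`` / ``age=None`` select the margin over that dimension;
    both ``None`` selects all natural-cause strata.
    """
    causes = CAUSES if cause is None else (cause,)
    ages = AGES if age is None else (age,)
    return [death_column(c, a) for c in causes for a in ages]
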