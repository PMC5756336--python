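"""Independently coded truth table for the auxotrophy-calling rule.

Kept separate from the implementation on purpose: this spells the rule
out case by case so the decision logic in the package can be checked
branch by branch against it.
"""

_TABLE = {
    # (missing steps, rescue outcome) -> status
    (0, "true"): "prototroph",
    (0, "false"): "prototroph",
    (0, "unavailable"): "prototroph",
    (1, "true"): "prototroph",       # gap explained by expression
    (1, "false"): "auxotroph",       # pathway transcribed too low
    (1, "unavailable"): "indeterminate",
    (2, "true"): "auxotroph",        # > 1 gene absent: always auxotroph
    (2, "false"): "auxotroph",
    (2, "unavailable"): "auxotroph",
}


def reference_decision_table(n_missing: int, rescue: str) -> str:
    return _TABLE[(min(n_missing, 2), rescue)]
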