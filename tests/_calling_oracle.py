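"""Independent brute-force re-implementation of the duplicate-well call
rules, written directly from their prose definitions and deliberately
structured differently from the package implementation (explicit None
for undetermined channels, per-rule helper functions, no shared code).
Used only as the oracle in equivalence tests."""

GENE_ORDER = ("mSEPT9", "mALX4", "mSDC2")


def _lt(ct, cutoff):
    return ct is not None and ct < cutoff


def _wells_valid(wells):
    for w in wells:
        actb = w["ACTB"]
        if actb is None or actb > 40:
            return False
    return True


def _delta(w, gene):
    if w[gene] is None or w["ACTB"] is None:
        return None
    return w[gene] - w["ACTB"]


def oracle_balancing(wells):
    if not _wells_valid(wells):
        return "INVALID"
    cut = {"mSEPT9": 45, "mALX4": 38, "mSDC2": 40}
    # (ii) test results positive for each well
    rule_ii = True
    for w in wells:
        if not any(_lt(w[g], cut[g]) for g in GENE_ORDER):
            rule_ii = False
    # (iii) mALX4 < 38 in a single test
    rule_iii = any(_lt(w["mALX4"], 38) for w in wells)
    # (iv) any two genes < 40 with delta CT < 10, within one well
    rule_iv = False
    for w in wells:
        qualifying = 0
        for g in GENE_ORDER:
            d = _delta(w, g)
            if _lt(w[g], 40) and d is not None and d < 10:
                qualifying += 1
        if qualifying >= 2:
            rule_iv = True
    return "POSITIVE" if (rule_ii or rule_iii or rule_iv) else "NEGATIVE"


def oracle_one_half(wells):
    if not _wells_valid(wells):
        return "INVALID"
    cut = {"mSEPT9": 45, "mALX4": 38, "mSDC2": 43}
    for w in wells:
        for g in GENE_ORDER:
            d = _delta(w, g)
            if _lt(w[g], cut[g]) and d is not None and d < 15:
                return "POSITIVE"
    return "NEGATIVE"


def oracle_two_thirds(wells):
    if not _wells_valid(wells):
        return "INVALID"
    cut = {"mSEPT9": 40.67, "mALX4": 36.8, "mSDC2": 36.23}
    for w in wells:
        if not any(_lt(w[g], cut[g]) for g in GENE_ORDER):
            return "NEGATIVE"
    return "POSITIVE"


ORACLES = {
    "balancing": oracle_balancing,
    "one_half": oracle_one_half,
    "two_thirds": oracle_two_thirds,
}


def record_to_dict(rec):
    """WellRecord -> plain dict with None for undetermined."""
    import math

    out = {}
    for gene in (*GENE_ORDER, "ACTB"):
        ct = rec.ct[gene]
        out[gene] = None if (isinstance(ct, float) and math.isnan(ct)) else ct
    return out
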