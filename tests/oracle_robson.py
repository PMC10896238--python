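"""Independent brute-force oracle for the Robson ten-group table.

Coded as a flat rule list straight from the published ten-group definitions
(one predicate per group, checked for mutual exclusivity by the tests), with
no code shared with the package's classifier.
"""

TERM = 37


def _parity(pvb, pcs):
    """Total parity; None when it cannot be established from the inputs."""
    if pcs is not None and pcs >= 1:
        return 1
    if pvb is not None and pvb >= 1:
        return 1
    if pvb is None or pcs is None:
        return None
    return 0


def oracle_group(plurality, presentation, ga, pcs, pvb, onset):
    """Return the Robson group 1..10, or None when required data is missing.

    Each group predicate is written independently from the published table:

    1  nulliparous, single cephalic, >=37w, spontaneous labour
    2  nulliparous, single cephalic, >=37w, induced or pre-labour CS
    3  multiparous (no prior CS), single cephalic, >=37w, spontaneous
    4  multiparous (no prior CS), single cephalic, >=37w, induced/pre-labour CS
    5  prior CS, single cephalic, >=37w
    6  nulliparous breech
    7  multiparous breech (including prior CS)
    8  multiple pregnancy (including prior CS)
    9  transverse or oblique lie (including prior CS)
    10 single cephalic preterm (<37w, including prior CS)
    """
    if plurality == "multiple":
        return 8
    if plurality is None:
        return None
    # singleton from here
    if presentation == "transverse_oblique":
        return 9
    if presentation is None:
        return None
    par = _parity(pvb, pcs)
    if presentation == "breech":
        if par is None:
            return None
        return 6 if par == 0 else 7
    # cephalic
    if ga is None:
        return None
    if ga < TERM:
        return 10
    if pcs is None:
        return None
    if pcs >= 1:
        return 5
    if par is None:
        return None
    if onset is None:
        return None
    spontaneous = onset == "spontaneous"
    if par == 0:
        return 1 if spontaneous else 2
    return 3 if spontaneous else 4


def full_cross_product():
    """Every combination of categorical inputs x GA 20..45 (plus missing)."""
    pluralities = ["single", "multiple", None]
    presentations = ["cephalic", "breech", "transverse_oblique", None]
    gas = list(range(20, 46)) + [None]
    pcs_values = [0, 1, 2, None]
    pvb_values = [0, 1, 4, None]
    onsets = ["spontaneous", "induced", "cesarean_before_labour", None]
    for plurality in pluralities:
        for presentation in presentations:
            for ga in gas:
                for pcs in pcs_values:
                    for pvb in pvb_values:
                        for onset in onsets:
                            yield (plurality, presentation, ga, pcs, pvb, onset)
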