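"""Naive position-by-position re-implementation of target rules r1-r5.

Deliberately written without numpy or any shared code path with
``heatmir.targets`` so it can serve as an independent oracle: plain
string comparison, explicit loops, literal thresholds.
"""

WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
WOBBLE = {("G", "T"), ("T", "G")}  # (miRNA, target), U as T


def naive_states(mirna: str, site: str) -> list[str]:
    """'match' / 'gu' / 'mm' per miRNA position (1-based order)."""
    assert len(mirna) == len(site)
    states = []
    n = len(mirna)
    for k in range(1, n + 1):
        m = mirna[k - 1]
        t = site[n - k]  # miRNA position k pairs the k-th base from 3' end
        if (m, t) in WC:
            states.append("match")
        elif (m, t) in WOBBLE:
            states.append("gu")
        else:
            states.append("mm")
    return states


def naive_accept_r1_r5(mirna: str, site: str) -> bool:
    """Rules 1-5 with G-U = 0.5 for the totals and a non-match for
    adjacency/central rules."""
    states = naive_states(mirna, site)
    score = sum(1.0 if s == "mm" else 0.5 if s == "gu" else 0.0
                for s in states)
    if score > 4:
        return False
    # rule 2: no more than 2 adjacent non-matches anywhere
    run = 0
    for s in states:
        run = run + 1 if s != "match" else 0
        if run > 2:
            return False
    # rule 3: no adjacent non-matches within positions 2-12
    for k in range(2, 12):  # pairs (k, k+1), both within 2..12
        if states[k - 1] != "match" and states[k] != "match":
            return False
    # rule 4: positions 10 and 11 must match
    if states[9] != "match" or states[10] != "match":
        return False
    # rule 5: no more than 2.5 over positions 1-12
    head = sum(1.0 if s == "mm" else 0.5 if s == "gu" else 0.0
               for s in states[:12])
    if head > 2.5:
        return False
    return True


def naive_windows(mirna: str, transcript: str) -> list[int]:
    """1-based start positions of windows accepted under r1-r5."""
    n = len(mirna)
    out = []
    for start in range(len(transcript) - n + 1):
        if naive_accept_r1_r5(mirna, transcript[start : start + n]):
            out.append(start + 1)
    return out
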