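import pytest

from parapep import FamilySpec, simulate_family, simulate_peptide_table


def brute_force_tryptic(seq, max_missed, min_len, max_len, proline_rule=True):
    """Independent all-substrings digestion oracle.

    Scans every substring and keeps exactly those with tryptic boundaries,
    within the length window and missed-cleavage budget. Deliberately naive.
    """
    n = len(seq)

    def competent(i):  # is the bond after 1-based residue i cleaved?
        return seq[i - 1] in "KR" and (not proline_rule or (i < n and seq[i] != "P"))

    out = set()
    for s in range(n):
        for e in range(s + 1, n + 1):
            pep = seq[s:e]
            if not (min_len <= len(pep) <= max_len) or "X" in pep:
                continue
            if not (s == 0 or competent(s)):
                continue
            if not (e == n or competent(e)):
                continue
            missed = sum(1 for i in range(s + 1, e) if competent(i))
            if missed <= max_missed:
                out.add((pep, s + 1))
    return out


@pytest.fixture
def default_family():
    spec = FamilySpec(seed=7)
    family = simulate_family(spec)
    observations = simulate_peptide_table(family.truth, spec)
    return spec, family, observations
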