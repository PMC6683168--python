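import pytest

from stoichioprot import SyntheticConfig, generate_study
from stoichioprot.elements import ElementCompositionTable


@pytest.fixture(scope="session")
def table():
    return ElementCompositionTable.default()


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared across tests (read-only)."""
    config = SyntheticConfig(n_proteins=400, seed=7)
    return generate_study(config)


#: free amino-acid molecular formulas, the independent oracle's raw data
FREE_AA_FORMULAS = {
    "A": "C3H7NO2", "R": "C6H14N4O2", "N": "C4H8N2O3", "D": "C4H7NO4",
    "C": "C3H7NO2S", "E": "C5H9NO4", "Q": "C5H10N2O3", "G": "C2H5NO2",
    "H": "C6H9N3O2", "I": "C6H13NO2", "L": "C6H13NO2", "K": "C6H14N2O2",
    "M": "C5H11NO2S", "F": "C9H11NO2", "P": "C5H9NO2", "S": "C3H7NO3",
    "T": "C4H9NO3", "W": "C11H12N2O2", "Y": "C9H11NO3", "V": "C5H11NO2",
}


def parse_formula(formula):
    """Parse e.g. 'C6H14N4O2' into an element->count dict."""
    import re

    counts = {}
    for elem, num in re.findall(r"([A-Z])(\d*)", formula):
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    return counts


def side_chain_atoms_oracle(residue, element):
    """Independent atom count: free AA formula minus H2O minus the chain
    backbone C2H2NO."""
    counts = parse_formula(FREE_AA_FORMULAS[residue])
    for sub in (parse_formula("H2O"), parse_formula("C2H2NO")):
        for elem, n in sub.items():
            counts[elem] = counts.get(elem, 0) - n
    return counts.get(element, 0)


def element_content_oracle(sequence, element):
    """Oracle for [E]: expand each residue's side-chain formula and count."""
    total = sum(side_chain_atoms_oracle(res, element) for res in sequence)
    return total / len(sequence)
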