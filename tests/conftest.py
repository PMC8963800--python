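import numpy as np
import pytest

from ppitex.pssm import AA_ORDER, PSSM, default_base_profile


@pytest.fixture(scope="session")
def base_profile():
    return default_base_profile()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_pssm_factory(rng):
    """Factory of random 20xM profiles spanning a PSSM-like value range."""

    def make(m, protein_id="px", low=-8, high=12):
        scores = rng.integers(low, high, size=(20, m)).astype(float)
        scores += rng.normal(0, 0.5, size=scores.shape)
        return PSSM(protein_id=protein_id, scores=scores)

    return make


@pytest.fixture()
def psiblast_fixture_file(tmp_path, rng):
    """Write a PSI-BLAST-style ASCII PSSM (independently of the library's
    writer) and return (path, expected 20xM matrix)."""
    m = 60
    residues = rng.choice(list(AA_ORDER), size=m)
    scores = rng.integers(-8, 12, size=(m, 20))
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted, and scaled",
        "            "
        + "   ".join(AA_ORDER)
        + "    "
        + "   ".join(AA_ORDER),
    ]
    for j in range(m):
        logodds = "  ".join(f"{v:3d}" for v in scores[j])
        pct = "  ".join("0" for _ in range(20))
        lines.append(f"{j + 1:5d} {residues[j]}  {logodds}   {pct}  0.36 0.07")
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.1337     0.3176"]
    path = tmp_path / "fixture.pssm"
    path.write_text("\n".join(lines) + "\n")
    return path, scores.T.astype(float)
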