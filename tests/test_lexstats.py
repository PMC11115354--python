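import numpy as np
import pandas as pd
import pytest

from cochmat.lexstats import (
    SamplerConfig,
    build_item_table,
    fit_item_regression,
    mean_phonological_distance,
    osa_distance,
)
from cochmat.synthgen import Lexicon

from .oracles import all_strings, osa_oracle


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("abc", "abc", 0),
        ("ab", "ba", 1),  # one adjacent transposition
        ("CA", "ABC", 3),  # OSA, not unrestricted Damerau-Levenshtein (2)
        ("", "abc", 3),
        ("abc", "", 3),
        ("kitten", "sitting", 3),
        ("abcd", "acbd", 1),
    ],
)
def test_osa_known_values(a, b, expected):
    assert osa_distance(a, b) == expected
    assert osa_distance(b, a) == expected  # symmetry


def test_osa_matches_exhaustive_search_on_random_pairs(rng):
    strings = all_strings("abc", 4)
    idx = rng.integers(0, len(strings), size=(400, 2))
    for i, j in idx:
        a, b = strings[i], strings[j]
        assert osa_distance(a, b) == osa_oracle(a, b), (a, b)


def test_osa_triangle_inequality_on_short_strings(rng):
    strings = all_strings("abc", 3)
    triples = rng.integers(0, len(strings), size=(500, 3))
    for i, j, k in triples:
        a, b, c = strings[i], strings[j], strings[k]
        assert osa_distance(a, c) <= osa_distance(a, b) + osa_distance(b, c)


def _lex(entries):
    return Lexicon(words=tuple(entries), transcriptions=tuple(entries), neighbor_pairs=())


def test_mean_phonological_distance():
    assert mean_phonological_distance("ab", _lex(["ab", "ba"])) == 1.0
    five = ["abc", "abd", "bca", "cab", "ccc"]
    expected = np.mean([osa_distance("abc", o) for o in five[1:]])
    assert mean_phonological_distance("abc", _lex(five)) == pytest.approx(expected)
    with pytest.raises(ValueError):
        mean_phonological_distance("ab", _lex(["ab"]))
    with pytest.raises(KeyError):
        mean_phonological_distance("zz", _lex(["ab", "ba"]))


def test_item_table_standardization():
    lex = _lex(["aaa", "bbb", "ccc", "abb", "bcc", "cca"])
    acc = {w: 50.0 + 5 * i for i, w in enumerate(lex.words)}
    counts = {w: 10 * (i + 1) for i, w in enumerate(lex.words)}
    table = build_item_table({"regular": acc, "delay": acc}, counts, lex)
    assert len(table) == 12
    for col in ("z_frequency", "z_distance"):
        per_word = table.drop_duplicates("word")[col]
        assert per_word.mean() == pytest.approx(0.0, abs=1e-9)
        assert per_word.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
    realized = table.groupby("word")["raw_frequency"].first().sort_index()
    assert (realized == pd.Series(counts).sort_index()).all()
    # uniform frequencies standardize to all-zero rather than dividing by zero
    uniform = build_item_table({"regular": acc, "delay": acc}, {w: 7 for w in lex.words}, lex)
    assert (uniform["z_frequency"] == 0).all()


def _synthetic_items(beta_f, beta_d, n_items, sigma, rng):
    rows = []
    zf = rng.standard_normal(n_items)
    zd = rng.standard_normal(n_items)
    for cond in ("regular", "delay"):
        for i in range(n_items):
            rows.append(
                dict(
                    word=f"w{i}",
                    condition=cond,
                    accuracy_percent=60 + beta_f * zf[i] + beta_d * zd[i] + rng.normal(0, sigma),
                    z_frequency=zf[i],
                    z_distance=zd[i],
                )
            )
    return pd.DataFrame(rows)


LIGHT = SamplerConfig(n_walkers=24, n_steps=2000, n_burn=1000)


def test_item_regression_recovers_planted_effect():
    table = _synthetic_items(beta_f=6.0, beta_d=0.0, n_items=35, sigma=2.0, rng=np.random.default_rng(42))
    post = fit_item_regression(table, LIGHT)
    lo, hi = post.credible_interval("beta_frequency")
    assert lo < 6.0 < hi
    assert post.summary.loc["beta_frequency", "mean"] == pytest.approx(6.0, abs=1.5)
    assert set(post.parameter_names) >= {
        "intercept",
        "beta_frequency",
        "beta_distance",
        "beta_cond[regular]",
        "omega",
        "alpha",
    }
    assert (post.summary["ci_2_5"] <= post.summary["ci_97_5"]).all()
    assert post.summary["rhat"].notna().all()


def test_item_regression_validates_inputs():
    table = _synthetic_items(0, 0, 10, 5.0, np.random.default_rng(1))
    with pytest.raises(ValueError):
        fit_item_regression(table[table.condition == "regular"], LIGHT)
    few = table[table.word.isin([f"w{i}" for i in range(4)])]
    with pytest.raises(ValueError):
        fit_item_regression(few, LIGHT)
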