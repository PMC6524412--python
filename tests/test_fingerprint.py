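import itertools
from collections import Counter

import numpy as np
import pytest
from sklearn.base import clone

from tifpscreen.fingerprint import (
    BinScheme,
    FeatureDictionary,
    Fingerprint,
    TifpVectorizer,
    TripletKey,
    append_descriptors,
    bin_distance,
    build_dictionary,
    canonical_triplet_key,
    enumerate_triplets,
    vectorize,
)
from tifpscreen.interactions import PSEUDOATOM_TYPES, Pseudoatom


def random_pseudoatoms(rng, n, box=25.0):
    return [
        Pseudoatom(ptype=str(rng.choice(PSEUDOATOM_TYPES)),
                   position=tuple(rng.uniform(0, box, 3)))
        for _ in range(n)
    ]


def bruteforce_key(p1, p2, p3, scheme=BinScheme()):
    """Independent canonicaliser: encode every vertex ordering, take the min string."""
    pts = [p1, p2, p3]
    encodings = []
    for perm in itertools.permutations(range(3)):
        parts = []
        for vi in perm:
            others = [v for v in perm if v != vi]
            d = float(np.linalg.norm(pts[others[0]].xyz - pts[others[1]].xyz))
            parts.append(f"{PSEUDOATOM_TYPES.index(pts[vi].ptype):02d}{bin_distance(d, scheme)}")
        encodings.append("".join(parts))
    return min(encodings)


class TestBinning:
    @pytest.mark.parametrize("d,expected", [
        (0.0, 0), (3.9, 0), (4.0, 1), (5.999, 1), (6.0, 2), (9.0, 3),
        (13.0, 4), (16.999, 4), (17.0, 5), (18.5, 5), (1000.0, 5),
    ])
    def test_half_open_bins(self, d, expected):
        assert bin_distance(d) == expected

    def test_negative_distance_errors(self):
        with pytest.raises(ValueError):
            bin_distance(-0.1)

    def test_bad_scheme_rejected(self):
        with pytest.raises(ValueError):
            BinScheme(edges=(6, 4, 9, 13, 17))
        with pytest.raises(ValueError):
            BinScheme(edges=(4, 6, 9))


class TestCanonicalKey:
    def test_all_permutations_identical(self):
        rng = np.random.default_rng(0)
        pts = [Pseudoatom("HYD", (0, 0, 0)), Pseudoatom("HBA", (5, 0, 0)),
               Pseudoatom("ARO", (0, 7, 0))]
        keys = {canonical_triplet_key(*[pts[i] for i in perm])
                for perm in itertools.permutations(range(3))}
        assert len(keys) == 1

    def test_equilateral_hyd_triangle(self):
        h = 5 * np.sqrt(3) / 2
        pts = [Pseudoatom("HYD", (0, 0, 0)), Pseudoatom("HYD", (5, 0, 0)),
               Pseudoatom("HYD", (2.5, h, 0))]
        key = canonical_triplet_key(*pts)
        assert key.sides == (("HYD", 1), ("HYD", 1), ("HYD", 1))

    def test_coincident_pseudoatoms_bin_zero(self):
        pts = [Pseudoatom("HYD", (0, 0, 0))] * 3
        assert canonical_triplet_key(*pts).sides == (("HYD", 0),) * 3

    def test_distinct_key_count_matches_bruteforce_canonicaliser(self):
        rng = np.random.default_rng(42)
        ours, brute = set(), set()
        for _ in range(1000):
            pts = random_pseudoatoms(rng, 3)
            ours.add(canonical_triplet_key(*pts).encode())
            brute.add(bruteforce_key(*pts))
        assert len(ours) == len(brute)

    def test_encode_decode_round_trip(self):
        key = TripletKey(sides=(("ARO", 2), ("HBD", 0), ("ION_N", 5)))
        assert TripletKey.decode(key.encode()) == key


class TestEnumeration:
    def test_fewer_than_three_gives_empty(self):
        rng = np.random.default_rng(0)
        assert enumerate_triplets(random_pseudoatoms(rng, 2)) == Counter()

    def test_three_gives_one(self):
        rng = np.random.default_rng(0)
        assert sum(enumerate_triplets(random_pseudoatoms(rng, 3)).values()) == 1

    def test_six_gives_twenty_matching_exhaustive_subsets(self):
        rng = np.random.default_rng(1)
        pts = random_pseudoatoms(rng, 6)
        got = enumerate_triplets(pts)
        assert sum(got.values()) == 20
        oracle = Counter()
        for combo in itertools.combinations(range(6), 3):
            oracle[bruteforce_key(*[pts[i] for i in combo])] += 1
        assert Counter({k.encode(): v for k, v in got.items()}) != Counter()
        # per-key multiplicities agree through the independent encoding
        assert sorted(got.values()) == sorted(oracle.values())
        assert len(got) == len(oracle)


class TestDictionary:
    def _multiset(self, *pairs):
        c = Counter()
        for encoded, n in pairs:
            c[TripletKey.decode(encoded)] += n
        return c

    def test_most_common_key_gets_index_zero(self):
        corpus = [self._multiset(("HYD:1|HYD:1|HYD:1", 10), ("HYD:0|HBA:2|ARO:1", 9))]
        d = build_dictionary(corpus, size=211)
        assert d.keys[0] == TripletKey.decode("HYD:1|HYD:1|HYD:1")

    def test_padding_to_211_with_inert_slots(self):
        corpus = [self._multiset((f"HYD:{i}|HYD:{i}|HYD:{i}", 5 - i)) for i in range(5)]
        d = build_dictionary(corpus, size=211)
        assert d.size == 211 and d.n_active == 5
        assert all(k is None for k in d.keys[5:])

    def test_count_tie_breaks_lexicographically_and_is_stable(self):
        corpus = [self._multiset(("HYD:2|HYD:2|HYD:2", 3), ("ARO:1|ARO:1|ARO:1", 3))]
        d1 = build_dictionary(corpus, size=4)
        d2 = build_dictionary(corpus, size=4)
        assert [k.encode() if k else None for k in d1.keys] == \
               [k.encode() if k else None for k in d2.keys]
        assert d1.keys[0].encode() < d1.keys[1].encode()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_dictionary([], size=211)
        with pytest.raises(ValueError):
            build_dictionary([Counter()], size=0)

    def test_json_round_trip(self, tmp_path):
        corpus = [self._multiset(("HYD:1|HBD:2|MET:0", 4))]
        d = build_dictionary(corpus, size=8, provenance="test")
        p = tmp_path / "dict.json"
        d.to_json(p)
        d2 = FeatureDictionary.from_json(p)
        assert [k.encode() if k else None for k in d.keys] == \
               [k.encode() if k else None for k in d2.keys]
        assert d2.counts == d.counts


class TestVectorize:
    def _dict_with(self, encoded_keys):
        corpus = [Counter({TripletKey.decode(k): n for n, k in enumerate(encoded_keys, start=1)})]
        return build_dictionary(corpus, size=211)

    def test_empty_multiset_zero_vector(self):
        d = self._dict_with(["HYD:1|HYD:1|HYD:1"])
        fp = vectorize(Counter(), d)
        assert len(fp.values) == 211 and not fp.values.any()

    def test_count_and_binary_modes(self):
        key = TripletKey.decode("HYD:1|HYD:1|HYD:1")
        d = self._dict_with(["HYD:1|HYD:1|HYD:1"])
        i = d.index_of(key)
        count_fp = vectorize(Counter({key: 3}), d, mode="count")
        binary_fp = vectorize(Counter({key: 3}), d, mode="binary")
        assert count_fp.values[i] == 3 and count_fp.values.sum() == 3
        assert binary_fp.values[i] == 1 and binary_fp.values.sum() == 1

    def test_count_conservation_with_dropped_keys(self):
        rng = np.random.default_rng(9)
        pts = random_pseudoatoms(rng, 12)
        keys = enumerate_triplets(pts)
        # dictionary built from a *different* configuration drops some keys
        d = build_dictionary([enumerate_triplets(random_pseudoatoms(rng, 10))], size=211)
        fp = vectorize(keys, d)
        dropped = sum(n for k, n in keys.items() if d.index_of(k) is None)
        assert fp.values.sum() + dropped == sum(keys.values()) == 220  # C(12,3)

    def test_append_descriptors(self):
        d = self._dict_with(["HYD:1|HYD:1|HYD:1"])
        fp = vectorize(Counter(), d)
        fp2 = append_descriptors(fp, [-8.9])
        assert len(fp2.values) == 212 and fp2.values[-1] == -8.9
        fp3 = append_descriptors(fp, [])
        np.testing.assert_array_equal(fp3.values, fp.values)
        with pytest.raises(ValueError):
            append_descriptors(fp, [float("nan")])


class TestVectorizerEstimator:
    def test_fit_transform_shapes_and_clone(self):
        rng = np.random.default_rng(2)
        corpus = [random_pseudoatoms(rng, rng.integers(4, 10)) for _ in range(6)]
        vec = TifpVectorizer()
        X = vec.fit_transform(corpus)
        assert X.shape == (6, 211)
        assert vec.dictionary_.size == 211
        cloned = clone(vec)
        assert cloned.get_params() == vec.get_params()
        with pytest.raises(ValueError, match="not fitted"):
            cloned.transform(corpus)

    def test_binary_mode(self):
        rng = np.random.default_rng(3)
        corpus = [random_pseudoatoms(rng, 8) for _ in range(4)]
        X = TifpVectorizer(mode="binary").fit_transform(corpus)
        assert set(np.unique(X)) <= {0.0, 1.0}
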