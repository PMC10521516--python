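import numpy as np
import pytest

from telarray.motif_scan import MotifCatalog, ScanParams
from telarray.synthetic_data import SimConfig, ZERO_ERRORS

# the 70-bp synthetic junction probe: (TTTAGGG)x5 + (TTTAAAA)x5
PROBE_70BP = "TTTAGGG" * 5 + "TTTAAAA" * 5


@pytest.fixture(scope="session")
def catalog() -> MotifCatalog:
    return MotifCatalog()


@pytest.fixture(scope="session")
def params() -> ScanParams:
    return ScanParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240911)


@pytest.fixture(scope="session")
def zero_error_config() -> SimConfig:
    return SimConfig(error_model=ZERO_ERRORS)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def plant_read(rng: np.random.Generator, *pieces) -> str:
    """Assemble tracts and random spacers into a read string whose spacer
    bases are screened so that no window crossing a tract boundary can seed
    or extend a scan (same discipline as the synthetic-read generator).

    ``pieces``: str items are planted verbatim (tracts); int items are
    random spacer lengths.
    """
    from telarray.motif_scan import MotifCatalog, ScanParams, compile_seed
    from telarray.synthetic_data import (
        _all_monomers_with_rc,
        _boundaries_ok,
        _random_dna,
    )

    catalog = MotifCatalog()
    params = ScanParams()
    mono = _all_monomers_with_rc(catalog)
    queries = [compile_seed(m, params.min_seed_copies) for m in catalog.seed_motifs]

    segments = []
    bounds = []  # (start, end) of each tract
    pos = 0
    for p in pieces:
        if isinstance(p, int):
            segments.append(_random_dna(rng, p))
            pos += p
        else:
            segments.append(np.frombuffer(p.encode(), dtype=np.uint8))
            bounds.append((pos, pos + len(p)))
            pos += len(p)
    arr = np.concatenate(segments)
    protected = np.zeros(len(arr), dtype=bool)
    for s, e in bounds:
        protected[s:e] = True

    from telarray.seqio import revcomp

    for _ in range(500):
        seq = arr.tobytes().decode()
        bad = [
            (s, e)
            for s, e in bounds
            if not _boundaries_ok(seq, s, e, mono, mono, params.max_monomer_edit_distance)
        ]
        if not bad and not any(
            q in seq[s:e] or revcomp(q) in seq[s:e]
            for (s, e) in _unprotected_runs(protected)
            for q in queries
        ):
            return seq
        regions = [r for s, e in bad for r in ((max(0, s - 22), s), (e, min(len(arr), e + 22)))]
        if not bad:  # a chance seed inside a spacer: resample all spacers
            regions = _unprotected_runs(protected)
        for lo, hi in regions:
            sel = ~protected[lo:hi]
            if sel.any():
                seg = arr[lo:hi]
                seg[sel] = _random_dna(rng, int(sel.sum()))
                arr[lo:hi] = seg
    raise RuntimeError("could not screen spacers")


def _unprotected_runs(protected: np.ndarray):
    runs, start = [], None
    for i, p in enumerate(protected):
        if not p and start is None:
            start = i
        elif p and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(protected)))
    return runs
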