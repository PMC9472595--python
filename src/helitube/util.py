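"""Small shared utilities: O(1) sampling sets and a buffered counter-based RNG."""

from __future__ import annotations

import numpy as np


class IndexedSet:
    """A set supporting O(1) add/discard/uniform-sample, backed by a list."""

    __slots__ = ("_items", "_pos")

    def __init__(self, items=()):
        self._items = []
        self._pos = {}
        for x in items:
            self.add(x)

    def add(self, x):
        if x not in self._pos:
            self._pos[x] = len(self._items)
            self._items.append(x)

    def discard(self, x):
        pos = self._pos.pop(x, None)
        if pos is None:
            return
        last = self._items.pop()
        if last is not x and pos < len(self._items):
            self._items[pos] = last
            self._pos[last] = pos

    def pick(self, u: float):
        """Return the element at fractional position ``u`` in [0, 1)."""
        return self._items[int(u * len(self._items))]

    def __len__(self):
        return len(self._items)

    def __contains__(self, x):
        return x in self._pos

    def __iter__(self):
        return iter(self._items)


class RandomPool:
    """Buffered uniform(0,1) stream over a counter-based bit generator (Philox).

    A single instance is the sole source of randomness of a simulation run, so
    a fixed seed reproduces trajectories bit-for-bit.
    """

    __slots__ = ("gen", "_buf", "_i", "_n", "seed")

    def __init__(self, seed: int, chunk: int = 8192):
        self.seed = seed
        self.gen = np.random.Generator(np.random.Philox(seed))
        self._n = chunk
        self._refill()

    def _refill(self):
        self._buf = self.gen.random(self._n)
        self._i = 0

    def u(self) -> float:
        """Next uniform float in [0, 1)."""
        if self._i >= self._n:
            self._refill()
        x = self._buf[self._i]
        self._i += 1
        return x

    def uniform(self, lo: float, hi: float) -> float:
        return lo + (hi - lo) * self.u()

    def index(self, n: int) -> int:
        return int(self.u() * n)

    def in_cube(self, half: float):
        """Uniform displacement in a cube of the given half-width."""
        return (
            self.uniform(-half, half),
            self.uniform(-half, half),
            self.uniform(-half, half),
        )

    def in_ball(self, radius: float):
        """Uniform displacement in a ball of the given radius (rejection)."""
        r2 = radius * radius
        while True:
            x = self.uniform(-radius, radius)
            y = self.uniform(-radius, radius)
            z = self.uniform(-radius, radius)
            if x * x + y * y + z * z <= r2:
                return (x, y, z)


def spawn_seed(master_seed: int, index: int) -> int:
    """Deterministic per-trial seed below 2**31 derived from (master, index)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)) + 1
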