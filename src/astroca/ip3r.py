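"""Eight-state IP3 receptor subunit Markov chain and stochastic channel gating.

Each IP3R channel consists of four identical subunits. A subunit carries three
binding sites — one for IP3, one activating Ca site, and one dominant
inhibiting Ca site — giving 2^3 occupancy states ``X_ijk`` (i: IP3 bound,
j: activating Ca bound, k: inhibiting Ca bound) connected by 12 reversible
transitions. A subunit is *active* only in ``X_110``; a channel is open when
at least three of its four subunits are active. Binding at the IP3 site and
the inhibiting site is allowed to depend on the occupancy of the other, which
produces the characteristic bell-shaped stationary open probability in the
Ca concentration.

Rate constants are not hard-coded here; they are read from the packaged
configuration (``dkm_rates`` block) or supplied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import default_config

#: state encoding: index = 4*i + 2*j + k
N_STATES = 8
ACTIVE_STATE = 6  # X_110
SUBUNITS_PER_CHANNEL = 4
OPEN_THRESHOLD = 3


@dataclass(frozen=True)
class SubunitState:
    """Occupancy triple of one subunit (the X_ijk index)."""

    ip3_bound: bool
    ca_act_bound: bool
    ca_inh_bound: bool

    @property
    def index(self) -> int:
        return 4 * self.ip3_bound + 2 * self.ca_act_bound + self.ca_inh_bound

    @property
    def active(self) -> bool:
        return self.index == ACTIVE_STATE

    @classmethod
    def from_index(cls, idx: int) -> "SubunitState":
        if not 0 <= idx < N_STATES:
            raise ValueError(f"state index {idx} outside 0..7")
        return cls(bool(idx & 4), bool(idx & 2), bool(idx & 1))


@dataclass(frozen=True)
class DKMRates:
    """Per-site rate constants of the subunit chain.

    Binding rates in 1/(uM s), unbinding rates in 1/s. ``*_inh_free`` /
    ``*_inh_bound`` distinguish the inhibiting-site occupancy for the IP3
    site; ``*_ip3_bound`` / ``*_ip3_free`` distinguish IP3 occupancy for the
    inhibiting site. The activating site is independent of the others.
    """

    ip3_on_inh_free: float = 400.0
    ip3_off_inh_free: float = 52.0
    ip3_on_inh_bound: float = 400.0
    ip3_off_inh_bound: float = 377.36
    act_on: float = 20.0
    act_off: float = 1.6468
    inh_on_ip3_bound: float = 0.2
    inh_off_ip3_bound: float = 0.2098
    inh_on_ip3_free: float = 0.2
    inh_off_ip3_free: float = 0.0289

    def __post_init__(self):
        vals = self.as_array()
        if np.any(vals < 0):
            raise ValueError("all rate constants must be non-negative")
        kd_act = self.act_off / self.act_on
        kd_inh = self.inh_off_ip3_bound / self.inh_on_ip3_bound
        if not kd_act < kd_inh:
            raise ValueError(
                "activating Ca site must have higher affinity (lower Kd) "
                f"than the dominant inhibiting site: {kd_act} >= {kd_inh}"
            )

    def as_array(self) -> np.ndarray:
        """Flat layout consumed by the numba kernel."""
        return np.array(
            [
                self.ip3_on_inh_free,
                self.ip3_off_inh_free,
                self.ip3_on_inh_bound,
                self.ip3_off_inh_bound,
                self.act_on,
                self.act_off,
                self.inh_on_ip3_bound,
                self.inh_off_ip3_bound,
                self.inh_on_ip3_free,
                self.inh_off_ip3_free,
            ]
        )

    @classmethod
    def from_config(cls, cfg: dict | None = None) -> "DKMRates":
        if cfg is None:
            cfg = default_config()["dkm_rates"]
        ip3 = cfg["ip3_site"]
        inh = cfg["ca_inhibiting_site"]
        act = cfg["ca_activating_site"]
        return cls(
            ip3_on_inh_free=ip3["on_inh_free"],
            ip3_off_inh_free=ip3["off_inh_free"],
            ip3_on_inh_bound=ip3["on_inh_bound"],
            ip3_off_inh_bound=ip3["off_inh_bound"],
            act_on=act["on"],
            act_off=act["off"],
            inh_on_ip3_bound=inh["on_ip3_bound"],
            inh_off_ip3_bound=inh["off_ip3_bound"],
            inh_on_ip3_free=inh["on_ip3_free"],
            inh_off_ip3_free=inh["off_ip3_free"],
        )


def subunit_generator(ca: float, ip3: float, rates: DKMRates) -> np.ndarray:
    """Infinitesimal generator (8x8) of one subunit at fixed ligand levels.

    Rows sum to zero; the off-diagonal support is the 12 reversible edges of
    the occupancy cube (24 directed entries).
    """
    if ca < 0 or ip3 < 0:
        raise ValueError("concentrations must be non-negative")
    a1, b1, a3, b3, a5, b5, a2, b2, a4, b4 = rates.as_array()
    Q = np.zeros((N_STATES, N_STATES))
    for s in range(N_STATES):
        i, j, k = (s >> 2) & 1, (s >> 1) & 1, s & 1
        # IP3 site
        if i == 0:
            Q[s, s | 4] = (a1 if k == 0 else a3) * ip3
        else:
            Q[s, s & ~4] = b1 if k == 0 else b3
        # activating Ca site
        if j == 0:
            Q[s, s | 2] = a5 * ca
        else:
            Q[s, s & ~2] = b5
        # inhibiting Ca site
        if k == 0:
            Q[s, s | 1] = (a2 if i == 1 else a4) * ca
        else:
            Q[s, s & ~1] = b2 if i == 1 else b4
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(ca: float, ip3: float, rates: DKMRates) -> np.ndarray:
    """Stationary distribution pi of the subunit chain (pi Q = 0, sum pi = 1)."""
    Q = subunit_generator(ca, ip3, rates)
    if np.allclose(Q, 0.0):
        raise ValueError("singular rate system: all transition rates are zero")
    # append the normalization constraint to the transposed generator
    A = np.vstack([Q.T, np.ones(N_STATES)])
    b = np.zeros(N_STATES + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def stationary_open_probability(ca: float, ip3: float, rates: DKMRates) -> float:
    """Stationary channel open probability.

    Subunits are treated as independent at stationarity, so with p the
    probability of one subunit being in X_110 the channel is open with
    probability C(4,3) p^3 (1-p) + p^4.
    """
    p = stationary_distribution(ca, ip3, rates)[ACTIVE_STATE]
    return float(4.0 * p**3 * (1.0 - p) + p**4)


@dataclass
class ChannelEnsembleState:
    """Subunit states of all channels of one cluster.

    ``states`` has shape (n_channels, 4) with entries in 0..7.
    """

    states: np.ndarray
    cluster_id: int = 0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2 or self.states.shape[1] != SUBUNITS_PER_CHANNEL:
            raise ValueError("states must have shape (n_channels, 4)")
        if self.states.max(initial=0) >= N_STATES:
            raise ValueError("state indices must be in 0..7")

    @property
    def n_channels(self) -> int:
        return self.states.shape[0]

    @property
    def n_active_per_channel(self) -> np.ndarray:
        return (self.states == ACTIVE_STATE).sum(axis=1)

    @property
    def channels_open(self) -> np.ndarray:
        return self.n_active_per_channel >= OPEN_THRESHOLD

    @property
    def n_open(self) -> int:
        return int(self.channels_open.sum())

    @property
    def n_subunits_active(self) -> int:
        return int((self.states == ACTIVE_STATE).sum())

    @classmethod
    def stationary(
        cls,
        n_channels: int,
        ca: float,
        ip3: float,
        rates: DKMRates,
        rng: np.random.Generator,
        cluster_id: int = 0,
    ) -> "ChannelEnsembleState":
        """Draw every subunit independently from the stationary distribution."""
        pi = stationary_distribution(ca, ip3, rates)
        states = rng.choice(N_STATES, size=(n_channels, SUBUNITS_PER_CHANNEL), p=pi)
        return cls(states=states.astype(np.uint8), cluster_id=cluster_id)

    @classmethod
    def resting(cls, n_channels: int, cluster_id: int = 0) -> "ChannelEnsembleState":
        """All sites unoccupied (X_000)."""
        return cls(
            states=np.zeros((n_channels, SUBUNITS_PER_CHANNEL), dtype=np.uint8),
            cluster_id=cluster_id,
        )


@dataclass(frozen=True)
class GatingEvent:
    """A channel open/close transition."""

    time: float
    cluster_id: int
    channel_id: int
    n_open_after: int


# ---------------------------------------------------------------------------
# numba kernels (shared with the spatial cell simulator)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _rng_uniform(state):
    """xorshift64* in (0, 1]; deterministic given the seed word."""
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    y = (x * np.uint64(2685821657736338717)) >> np.uint64(11)
    return (np.float64(y) + 1.0) / 9007199254740992.0


def seed_rng_state(seed: int) -> np.ndarray:
    """Expand a small integer seed into a nonzero 64-bit generator word."""
    mix = np.uint64((seed * 0x9E3779B97F4A7C15 + 0xBF58476D1CE4E5B9) % 2**64)
    if mix == 0:
        mix = np.uint64(0x853C49E6748FEA9B)
    return np.array([mix], dtype=np.uint64)


@njit(cache=True)
def _site_rates(s, ca, ip3, rc):
    """Rates of the three possible toggles out of state ``s``."""
    i = (s >> 2) & 1
    j = (s >> 1) & 1
    k = s & 1
    if i == 0:
        r0 = (rc[0] if k == 0 else rc[2]) * ip3
    else:
        r0 = rc[1] if k == 0 else rc[3]
    r1 = rc[4] * ca if j == 0 else rc[5]
    if k == 0:
        r2 = (rc[6] if i == 1 else rc[8]) * ca
    else:
        r2 = rc[7] if i == 1 else rc[9]
    return r0, r1, r2


@njit(cache=True)
def gating_ssa_collect(
    states,  # (n_subunits,) uint8, flat; subunit s belongs to channel s // 4
    sub_cluster,  # (n_subunits,) int64 cluster index per subunit
    n_active,  # (n_channels,) int64 number of active subunits per channel
    ca_cl,  # (n_clusters,) local Ca seen by each cluster
    ip3,
    rate_consts,  # flat 10-vector, see DKMRates.as_array
    t0,
    t_end,
    rng_state,
    stop_on_open_change,
    ev_times,  # preallocated output buffers for open/close events
    ev_channels,
):
    """Exact SSA with frozen propensities.

    Returns ``(t, n_events, transitions)``. Channel open/close flips are
    written to the event buffers; if ``stop_on_open_change`` the walk stops
    at the first flip. ``transitions`` counts all subunit transitions.
    """
    n_sub = states.shape[0]
    cap = ev_times.shape[0]
    n_ev = 0
    exit_rates = np.empty(n_sub)
    total = 0.0
    for s in range(n_sub):
        r0, r1, r2 = _site_rates(states[s], ca_cl[sub_cluster[s]], ip3, rate_consts)
        exit_rates[s] = r0 + r1 + r2
        total += exit_rates[s]
    t = t0
    transitions = 0
    while True:
        if total <= 0.0:
            return t_end, n_ev, transitions
        u = _rng_uniform(rng_state)
        t = t - np.log(u) / total
        if t >= t_end:
            return t_end, n_ev, transitions
        # pick a subunit proportionally to its exit rate
        target = _rng_uniform(rng_state) * total
        acc = 0.0
        chosen = n_sub - 1
        for s in range(n_sub):
            acc += exit_rates[s]
            if acc >= target:
                chosen = s
                break
        ca = ca_cl[sub_cluster[chosen]]
        r0, r1, r2 = _site_rates(states[chosen], ca, ip3, rate_consts)
        rem = acc - target  # in [0, exit_rates[chosen])
        if rem < r2:
            new_state = states[chosen] ^ np.uint8(1)
        elif rem < r2 + r1:
            new_state = states[chosen] ^ np.uint8(2)
        else:
            new_state = states[chosen] ^ np.uint8(4)
        old_state = states[chosen]
        states[chosen] = new_state
        transitions += 1
        ch = chosen // 4
        was_open = n_active[ch] >= OPEN_THRESHOLD
        if old_state == ACTIVE_STATE:
            n_active[ch] -= 1
        if new_state == ACTIVE_STATE:
            n_active[ch] += 1
        now_open = n_active[ch] >= OPEN_THRESHOLD
        # refresh this subunit's propensities
        n0, n1, n2 = _site_rates(new_state, ca, ip3, rate_consts)
        new_exit = n0 + n1 + n2
        total += new_exit - exit_rates[chosen]
        exit_rates[chosen] = new_exit
        if was_open != now_open:
            if n_ev < cap:
                ev_times[n_ev] = t
                ev_channels[n_ev] = ch
                n_ev += 1
            if stop_on_open_change or n_ev >= cap:
                return t, n_ev, transitions


def events_to_frame(events):
    """Gating events as a DataFrame (time, cluster_id, channel_id,
    n_open_after), ready for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "time": e.time,
                "cluster_id": e.cluster_id,
                "channel_id": e.channel_id,
                "n_open_after": e.n_open_after,
            }
            for e in events
        ],
        columns=["time", "cluster_id", "channel_id", "n_open_after"],
    )


def gating_ssa(
    states,
    sub_cluster,
    n_active,
    ca_cl,
    ip3,
    rate_consts,
    t0,
    t_end,
    rng_state,
    stop_on_open_change,
):
    """Compatibility wrapper returning ``(t, channel, transitions)``.

    ``channel`` is the first channel whose open status flipped, or −1 when
    the interval completed without a flip (or flips were not requested).
    """
    ev_t = np.empty(1024)
    ev_c = np.empty(1024, dtype=np.int64)
    t = t0
    transitions = 0
    first = -1
    while True:
        t, n_ev, tr = gating_ssa_collect(
            states, sub_cluster, n_active, ca_cl, ip3, rate_consts,
            t, t_end, rng_state, stop_on_open_change, ev_t, ev_c,
        )
        transitions += tr
        if n_ev and first < 0:
            first = int(ev_c[0])
        if stop_on_open_change and n_ev:
            return t, first, transitions
        if t >= t_end:
            return t_end, -1, transitions


def simulate_gating(
    ensemble: ChannelEnsembleState,
    local_ca,
    ip3: float,
    t0: float,
    t1: float,
    rng_seed: int,
    rates: DKMRates | None = None,
):
    """Simulate stochastic gating under a piecewise-constant Ca signal.

    ``local_ca`` is a sequence of ``(t_start, t_end, ca)`` segments that must
    cover ``[t0, t1]`` contiguously. Returns ``(events, final_ensemble)``
    where events is a time-ordered list of :class:`GatingEvent`.
    """
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    if rates is None:
        rates = DKMRates.from_config()
    segments = [(float(a), float(b), float(c)) for a, b, c in local_ca]
    segments.sort()
    # validate coverage
    cursor = t0
    covering = []
    for a, b, c in segments:
        if b <= cursor:
            continue
        if a > cursor + 1e-12:
            raise ValueError(f"local_ca undefined on [{cursor}, {a}]")
        covering.append((max(a, cursor), min(b, t1), c))
        cursor = min(b, t1)
        if cursor >= t1:
            break
    if cursor < t1 - 1e-12:
        raise ValueError(f"local_ca undefined on [{cursor}, {t1}]")

    states = ensemble.states.copy().reshape(-1)
    n_ch = ensemble.n_channels
    sub_cluster = np.zeros(states.size, dtype=np.int64)
    n_active = (
        (states.reshape(n_ch, SUBUNITS_PER_CHANNEL) == ACTIVE_STATE)
        .sum(axis=1)
        .astype(np.int64)
    )
    rng_state = seed_rng_state(rng_seed)
    rc = rates.as_array()
    events: list[GatingEvent] = []
    for a, b, ca in covering:
        if ca < 0:
            raise ValueError("negative Ca concentration")
        t = a
        while t < b:
            t, ch, _ = gating_ssa(
                states,
                sub_cluster,
                n_active,
                np.array([ca]),
                ip3,
                rc,
                t,
                b,
                rng_state,
                True,
            )
            if ch >= 0:
                n_open = int((n_active >= OPEN_THRESHOLD).sum())
                events.append(
                    GatingEvent(t, ensemble.cluster_id, int(ch), n_open)
                )
    final = ChannelEnsembleState(
        states=states.reshape(n_ch, SUBUNITS_PER_CHANNEL),
        cluster_id=ensemble.cluster_id,
    )
    return events, final
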