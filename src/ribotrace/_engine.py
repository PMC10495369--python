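"""Per-mRNA stochastic elongation engines.

Two exact samplers of the same mechanistic model:

* :func:`simulate_rna_excluded` -- event-driven loop with steric
  exclusion (a ribosome cannot step within ``footprint`` codons of the
  one ahead; initiation attempts that find the entry window occupied are
  aborted).  Dwell per codon is exponential with mean 1/v (Gillespie) or
  exactly 1/v in deterministic-stepping mode.
* :func:`simulate_rna_free` -- vectorised sampler of the identical model
  without exclusion (ribosomes are independent); used automatically when
  exclusion is switched off.

Both return a list of ribosome records:
``(init_time, is_ran, fs_codon_or_None, end_time, ch1_times, ch2_times)``
where ``chX_times`` are the completion times of each epitope the
ribosome translated, in codon order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulate_rna_excluded", "simulate_rna_free", "telegraph_intervals", "poisson_times"]


def telegraph_intervals(k_on: float, k_off: float, duration: float, rng) -> list[tuple[float, float, bool]]:
    """ON/OFF intervals (start, end, is_on) tiling [0, duration].

    The initial state is drawn from the stationary distribution; with
    both rates zero the switch is permanently ON (no bursting).
    """
    if k_on == 0.0 and k_off == 0.0:
        return [(0.0, duration, True)]
    p_on = 1.0 if k_off == 0.0 else (0.0 if k_on == 0.0 else k_on / (k_on + k_off))
    on = bool(rng.random() < p_on)
    out = []
    t = 0.0
    while t < duration:
        rate = k_off if on else k_on
        dt = np.inf if rate == 0.0 else rng.exponential(1.0 / rate)
        end = min(t + dt, duration)
        out.append((t, end, on))
        t = end
        on = not on
    return out


def poisson_times(rate: float, intervals, rng, t_max: float | None = None) -> np.ndarray:
    """Homogeneous Poisson event times within the given (start, end) windows."""
    times = []
    for iv in intervals:
        a, b = iv[0], iv[1]
        if t_max is not None:
            b = min(b, t_max)
        if b <= a or rate <= 0.0:
            continue
        n = rng.poisson(rate * (b - a))
        if n:
            times.append(a + (b - a) * rng.random(n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def _dwell(rng, mean: float, deterministic: bool) -> float:
    return mean if deterministic else rng.exponential(mean)


def simulate_rna_excluded(
    speeds: np.ndarray,
    eps1: np.ndarray,
    eps2: np.ndarray,
    ch1_stop: int,
    total_length: int,
    insert_start: int,
    insert_end: int,
    fs_hazard: float,
    footprint: int,
    init_times: np.ndarray,
    ran_times: np.ndarray,
    ran_start: int,
    rng,
    deterministic: bool = False,
):
    """Event-driven simulation honouring the steric footprint."""
    eps1_set = set(int(p) for p in eps1)
    eps2_set = set(int(p) for p in eps2)
    # pending initiations: (time, is_ran); ran ribosomes enter at ran_start-1
    pend = sorted(
        [(float(t), False) for t in init_times] + [(float(t), True) for t in ran_times]
    )
    ip = 0
    # active ribosomes, leading first: [pos, next_t, stop, fs_codon, is_ran,
    #                                   init_time, ch1_times, ch2_times]
    ribs: list[list] = []
    records = []
    inv_v = 1.0 / speeds  # mean dwell per codon (index 0 = codon 1)

    def blocked(i: int) -> bool:
        # ribosome i wants to occupy pos+1; requires gap to leader > footprint
        if i == 0:
            return False
        return ribs[i - 1][0] - ribs[i][0] <= footprint

    while True:
        t_step = np.inf
        k = -1
        for i, r in enumerate(ribs):
            if r[1] < t_step:
                t_step = r[1]
                k = i
        t_init = pend[ip][0] if ip < len(pend) else np.inf
        if t_init == np.inf and t_step == np.inf:
            break

        if t_init <= t_step:
            t, is_ran = pend[ip]
            ip += 1
            entry = ran_start - 1 if is_ran else 0
            # abortive if any ribosome sits within one footprint of the entry
            if any(abs(r[0] - entry) < footprint for r in ribs):
                continue
            stop = total_length if is_ran else ch1_stop
            nr = [entry, t + _dwell(rng, inv_v[entry], deterministic), stop, None,
                  is_ran, t, [], []]
            # insert keeping ribs ordered by descending position
            j = len(ribs)
            while j > 0 and ribs[j - 1][0] < entry:
                j -= 1
            ribs.insert(j, nr)
            continue

        # elongation step of ribosome k
        r = ribs[k]
        if blocked(k):
            # became blocked since its dwell was drawn: wait for leader
            r[1] = np.inf
            continue
        r[0] += 1
        pos = r[0]
        t = t_step
        if (r[3] is None and not r[4] and fs_hazard > 0.0
                and insert_start <= pos <= insert_end and rng.random() < fs_hazard):
            r[3] = pos           # frameshift at this codon
            r[2] = total_length  # continues into the downstream frame
        if pos in eps1_set:
            r[6].append(t)
        if pos in eps2_set:
            r[7].append(t)
        if pos >= r[2]:
            records.append((r[5], r[4], r[3], t,
                            np.asarray(r[6]), np.asarray(r[7])))
            ribs.pop(k)
            if k < len(ribs) and ribs[k][1] == np.inf and not blocked(k):
                ribs[k][1] = t + _dwell(rng, inv_v[ribs[k][0]], deterministic)
            continue
        r[1] = np.inf if blocked(k) else t + _dwell(rng, inv_v[pos], deterministic)
        # the follower may now be free to move
        if k + 1 < len(ribs) and ribs[k + 1][1] == np.inf and not blocked(k + 1):
            f = ribs[k + 1]
            f[1] = t + _dwell(rng, inv_v[f[0]], deterministic)

    return records


def simulate_rna_free(
    speeds: np.ndarray,
    eps1: np.ndarray,
    eps2: np.ndarray,
    ch1_stop: int,
    total_length: int,
    insert_start: int,
    insert_end: int,
    fs_hazard: float,
    init_times: np.ndarray,
    ran_times: np.ndarray,
    ran_start: int,
    rng,
    deterministic: bool = False,
):
    """Vectorised independent-ribosome sampler (no steric exclusion)."""
    records = []
    inv_v = 1.0 / speeds
    eps1 = np.asarray(eps1, dtype=int)
    eps2 = np.asarray(eps2, dtype=int)
    n = len(init_times)

    # decide frameshift codon per cap-initiated ribosome by geometric draw
    if n:
        L_ins = max(0, insert_end - insert_start + 1)
        if fs_hazard > 0.0 and L_ins > 0:
            # first-success codon index within the insert (1-based), or 0 = none
            u = rng.random(n)
            with np.errstate(divide="ignore"):
                g = np.floor(np.log1p(-u) / np.log1p(-fs_hazard)).astype(int) + 1
            fs_codon = np.where(g <= L_ins, insert_start - 1 + g, 0)
        else:
            fs_codon = np.zeros(n, dtype=int)

        for i in range(n):
            stop = total_length if fs_codon[i] else ch1_stop
            if deterministic:
                dwell = inv_v[:stop]
            else:
                dwell = rng.exponential(inv_v[:stop])
            arrival = init_times[i] + np.cumsum(dwell)  # arrival[j] = codon j+1 done
            e1 = arrival[eps1[eps1 <= stop] - 1]
            e2 = arrival[eps2[eps2 <= stop] - 1] if (fs_codon[i] and len(eps2)) else np.empty(0)
            records.append((float(init_times[i]), False,
                            int(fs_codon[i]) if fs_codon[i] else None,
                            float(arrival[-1]), e1, e2))

    for t0 in ran_times:
        path = slice(ran_start - 1, total_length)
        if deterministic:
            dwell = inv_v[path]
        else:
            dwell = rng.exponential(inv_v[path])
        arrival = float(t0) + np.cumsum(dwell)
        sel = eps2[eps2 >= ran_start]
        e2 = arrival[sel - ran_start]
        records.append((float(t0), True, None, float(arrival[-1]), np.empty(0), e2))

    records.sort(key=lambda r: r[0])
    return records
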