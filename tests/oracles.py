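"""Independent reference implementations used only for cross-checking.

Everything here is deliberately written from first principles (plain loops,
scipy generic optimizers/integrators, textbook formulas) and stays
independent of the package's vectorized estimation path.
"""

import math

import numpy as np
from scipy import integrate, optimize


def conc_superposition(dose, interval, n_doses, cl, v, ka, t):
    """Concentration after ``n_doses`` repeated doses by explicit summation."""
    k = cl / v
    total = 0.0
    for m in range(n_doses):
        td = t + m * interval
        total += dose * ka / (v * (ka - k)) * (math.exp(-k * td)
                                               - math.exp(-ka * td))
    return total


def conc_ode(dose, cl, v, ka, t_grid):
    """Single-dose profile by numerically integrating the gut/central ODEs."""
    k = cl / v

    def rhs(t, y):
        gut, central = y
        return [-ka * gut, ka * gut - k * central]

    sol = integrate.solve_ivp(rhs, (0.0, float(max(t_grid))), [dose, 0.0],
                              t_eval=t_grid, rtol=1e-10, atol=1e-12)
    return sol.y[1] / v


def subject_neg2_log_joint(model, y, t, dose, tau, ss, weight, eta):
    """-2 log [p(y | eta) p(eta)] for one subject, plain-Python."""
    fw = weight / model.reference_weight
    cl = model.theta_cl * fw ** model.allometric_cl * math.exp(eta[0])
    v = model.theta_v * fw ** model.allometric_v * math.exp(eta[1])
    ka = model.theta_ka + cl / v
    k = cl / v
    val = 0.0
    for yj, tj in zip(y, t):
        tt = tj % tau if ss else tj
        if ss:
            f = dose * ka / (v * (ka - k)) * (
                math.exp(-k * tt) / (1 - math.exp(-k * tau))
                - math.exp(-ka * tt) / (1 - math.exp(-ka * tau)))
        else:
            f = dose * ka / (v * (ka - k)) * (math.exp(-k * tt)
                                              - math.exp(-ka * tt))
        var = model.sigma2_prop * f * f + model.sigma2_add
        val += math.log(2 * math.pi * var) + (yj - f) ** 2 / var
    val += (2 * math.log(2 * math.pi)
            + math.log(model.omega2_cl * model.omega2_v)
            + eta[0] ** 2 / model.omega2_cl + eta[1] ** 2 / model.omega2_v)
    return val


def ofv_agq_reference(model, dataset, n_nodes=17):
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    Mode finding uses Nelder-Mead, curvature comes from plain finite
    differences, and the quadrature grid is the tensor product of
    ``n_nodes`` Hermite-Gauss nodes per dimension.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    df = dataset.df
    for sid, g in df.groupby("ID", sort=False):
        dose_rows = g[g["EVID"] == 1]
        obs = g[g["EVID"] == 0]
        if not len(obs):
            continue
        dose = float(dose_rows["AMT"].iloc[0])
        ss = bool(int(dose_rows["SS"].iloc[0]))
        tau = float(dose_rows["II"].iloc[0]) if ss else 24.0
        weight = float(g["WT"].iloc[0])
        y = obs["DV"].to_numpy(dtype=float)
        t = obs["TIME"].to_numpy(dtype=float)

        def nll(eta):
            return subject_neg2_log_joint(model, y, t, dose, tau, ss,
                                          weight, eta)

        res = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 2000})
        mode = res.x
        h = 1e-4
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.zeros(2); ei[i] = h
                ej = np.zeros(2); ej[j] = h
                H[i, j] = (nll(mode + ei + ej) - nll(mode + ei - ej)
                           - nll(mode - ei + ej) + nll(mode - ei - ej)) / (4 * h * h)
        cov = np.linalg.inv(H / 2.0)
        L = np.linalg.cholesky(cov)
        val = 0.0
        for a, wa in zip(nodes, weights):
            for b, wb in zip(nodes, weights):
                eta = mode + math.sqrt(2.0) * (L @ np.array([a, b]))
                val += wa * wb * math.exp(a * a + b * b - 0.5 * nll(eta))
        log_li = math.log(val) + math.log(2.0) + 0.5 * np.linalg.slogdet(cov)[1]
        total += -2.0 * log_li
    return total


def km_by_hand(times, events):
    """Product-limit estimate as (time, survival) pairs, textbook loop."""
    order = np.argsort(times)
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=bool)[order]
    s = 1.0
    out = []
    for t in np.unique(times):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        if d > 0:
            s *= 1.0 - d / at_risk
            out.append((t, s))
    return out


def logrank_by_hand(times_a, events_a, times_b, events_b):
    """Log-rank chi-square by explicit summation over risk sets."""
    ta = np.asarray(times_a, dtype=float); ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float); eb = np.asarray(events_b, dtype=bool)
    all_t = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_t:
        n1 = np.sum(ta >= t); n2 = np.sum(tb >= t)
        d1 = np.sum((ta == t) & ea); d2 = np.sum((tb == t) & eb)
        n = n1 + n2; d = d1 + d2
        if n < 1 or n == 1:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return o_minus_e ** 2 / var if var > 0 else 0.0


def rmst_rectangles(km_pairs, tau):
    """Area under a step survival curve on [0, tau] by rectangle sums."""
    area = 0.0
    prev_t, prev_s = 0.0, 1.0
    for t, s in km_pairs:
        if t >= tau:
            break
        area += prev_s * (t - prev_t)
        prev_t, prev_s = t, s
    area += prev_s * (tau - prev_t)
    return area
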