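import pytest

from stripquant import default_b12_curve


@pytest.fixture()
def reference_curve():
    """The built-in B12 batch calibration (a=0.99, b=3, c=303.7, d=0.3)."""
    return default_b12_curve()


def brute_force_minima(values, min_depth=10.0):
    """Independent enumeration oracle for prominent local minima.

    For every index, checks directly whether it is the centre of a plateau
    strictly below both neighbouring values, then scans outward on each side
    for the longest non-rising stretch to find the enclosing turning-point
    baselines, and filters by bilateral prominence >= min_depth.  Returns
    (centre, min_value, left_baseline, right_baseline) tuples.
    """
    n = len(values)
    out = []
    for s in range(1, n - 1):
        if values[s] == values[s - 1]:
            continue  # not the start of a run
        e = s
        while e + 1 < n and values[e + 1] == values[s]:
            e += 1
        if e == n - 1:
            continue  # run touches the boundary
        if not (values[s - 1] > values[s] and values[e + 1] > values[s]):
            continue  # not a local minimum
        lb = values[s]
        for j in range(s - 1, -1, -1):
            if values[j] >= lb:
                lb = values[j]
            else:
                break
        rb = values[e]
        for j in range(e + 1, n):
            if values[j] >= rb:
                rb = values[j]
            else:
                break
        if lb - values[s] >= min_depth and rb - values[s] >= min_depth:
            out.append(((s + e) // 2, float(values[s]), float(lb), float(rb)))
    return out
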