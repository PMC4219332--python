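# Derivation of the inner dual and the coupling equality

The inner problem, for a fixed dosage vector `h`, is the L1 minimal
adjustment LP over the restricted flux set `W(h)`:

```
min  sum_i a_i
s.t. S v = 0                                  (steady state)
     v_j <= U_j                      for all j (bounds)
     v_i <= U_i (1 - h_k)            for all (drug k, target i) pairs
     v_j - a_j <=  v_ut_j            for all j (abs-value, +)
    -v_j - a_j <= -v_ut_j            for all j (abs-value, -)
     v, a >= 0
```

To apply the strong duality theorem in the standard form
`max {c.x : A x <= b, x >= 0} = min {b.theta : A^T theta >= c}`, rewrite
the inner minimum as `max -sum_i a_i`, keeping the equalities with free
dual variables.  Associate dual variables as follows:

| primal row                  | dual variable | sign  |
|-----------------------------|---------------|-------|
| steady state (per met i)    | `mu_i`        | free  |
| `v_j <= U_j`                | `lam_j`       | >= 0  |
| `v_i <= U_i (1 - h_k)`      | `delta_p`     | >= 0  (one per (k, i) pair) |
| `v_j - a_j <= v_ut_j`       | `alpha_j`     | >= 0  |
| `-v_j - a_j <= -v_ut_j`     | `beta_j`      | >= 0  |

Dual feasibility `A^T theta >= c` gives one row per primal column:

* column `v_j` (objective coefficient 0):

  ```
  sum_i S_ij mu_i + lam_j + sum_{p : target(p) = j} delta_p + alpha_j - beta_j >= 0
  ```

* column `a_j` (objective coefficient -1):

  ```
  -alpha_j - beta_j >= -1      i.e.     alpha_j + beta_j <= 1
  ```

The dual objective is

```
b.theta = sum_j U_j lam_j + sum_p U_{i(p)} (1 - h_{k(p)}) delta_p
          + sum_j v_ut_j (alpha_j - beta_j)
```

and strong duality at the inner optimum states `-sum_i a_i = b.theta`,
i.e. the coupling equality used in the single-level model:

```
sum_i a_i + sum_j U_j lam_j + sum_p U_{i(p)} (1 - h_{k(p)}) delta_p
          + sum_j v_ut_j (alpha_j - beta_j) = 0
```

The leading sign follows directly from the max form of the primal; it is
verified numerically in the test suite by solving the primal and dual LPs
separately for fixed `h` and checking that the optimal values are equal
and opposite.

## Linearization

The only bilinear terms are `delta_p * h_k`.  Expanding `h_k` over its
Boolean dosage variables with decoding weights `w_n`
(`h_k = sum_n w_n x_{k,n}`) spreads the nonlinearity over products
`delta_p * x_{k,n}` of a bounded continuous variable and a Boolean.  Each
product is replaced by an auxiliary variable `z_{p,n}` with the exact
big-M relations (`M = delta_max_p`, a valid upper bound for `delta_p`):

```
0 <= z_{p,n} <= delta_max_p * x_{k,n}
delta_p - delta_max_p * (1 - x_{k,n}) <= z_{p,n} <= delta_p
```

With `x = 0` these force `z = 0`; with `x = 1` they force `z = delta_p`.
The coupling equality is then written with
`delta_p * h_k = sum_n w_n z_{p,n}`.

`delta_max` defaults to the conservative uniform bound
`max(1, kappa * max_j U_j)`; the solver warns when an optimal `delta`
comes within 1% of its bound, and every reported optimum is re-validated
by an independent forward L1 solve at the returned dosage vector, so an
insufficient bound cannot silently corrupt a result.
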