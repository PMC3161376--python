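name: antid
outcome: antid
strategies:
- - '1'
  - No routine AADP (conventional management)
- - '2'
  - AADP to primigravidae only
- - '3'
  - AADP to all RhD-negative pregnant women
treatments:
- - partobulin
  - Partobulin
- - rhophylac
  - Rhophylac
- - dgam
  - D-Gam
- - winrho
  - WinRho
parameters:
- name: s0
  distribution: beta
  params:
    alpha: 9.5
    beta: 990.5
  description: baseline sensitization probability
- name: or_eff
  distribution: lognormal
  params:
    mu: -0.936290731874155
    sigma: 0.2
  description: effectiveness odds ratio (shared by all products)
- name: p_prim
  distribution: beta
  params:
    alpha: 40.0
    beta: 60.0
  description: proportion primigravidae
- name: p_subseq
  distribution: beta
  params:
    alpha: 70.0
    beta: 30.0
  description: P(subsequent RhD+ pregnancy | sensitized)
- name: p_affected
  distribution: beta
  params:
    alpha: 60.0
    beta: 40.0
  description: P(HDN-affected fetus | sensitized)
- name: p_loss
  distribution: beta
  params:
    alpha: 5.0
    beta: 95.0
  description: P(fetal loss | affected)
- name: q_affected
  distribution: gamma
  params:
    shape: 16.0
    rate: 8.0
  description: QALY loss per affected fetus
- name: q_loss
  distribution: gamma
  params:
    shape: 25.0
    rate: 1.0
  description: QALY loss per fetal loss
- name: ly_loss
  distribution: point
  params:
    value: 75.0
  description: life-years lost per fetal loss
- name: d_eff
  distribution: point
  params:
    value: 0.035
  low: 0.0
  high: 0.07
  description: annual discount rate, effects
- name: d_cost
  distribution: point
  params:
    value: 0.035
  low: 0.0
  high: 0.07
  description: annual discount rate, costs
- name: t_lag
  distribution: point
  params:
    value: 2.0
  description: years to subsequent pregnancy
- name: n_doses
  distribution: point
  params:
    value: 2.0
  description: doses per covered pregnancy
- name: c_admin
  distribution: gamma
  params:
    shape: 25.0
    rate: 5.0
  description: administration cost per dose
- name: c_sens
  distribution: gamma
  params:
    shape: 100.0
    rate: 0.034482758620689655
  description: lifetime management cost per sensitized woman
- name: c_hdn
  distribution: gamma
  params:
    shape: 100.0
    rate: 0.006666666666666667
  description: cost per HDN-affected fetus
- name: cohort
  distribution: point
  params:
    value: 100000.0
  description: women per run
- name: c_dose_partobulin
  distribution: point
  params:
    value: 27.5
  description: cost per dose, Partobulin
- name: c_dose_rhophylac
  distribution: point
  params:
    value: 35.0
  description: cost per dose, Rhophylac
- name: c_dose_dgam
  distribution: point
  params:
    value: 22.0
  description: cost per dose, D-Gam
- name: c_dose_winrho
  distribution: point
  params:
    value: 40.0
  description: cost per dose, WinRho
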