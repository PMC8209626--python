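costs: {diagnosis_workup: 1200.0, follow_up_annual: 350.0, follow_up_years: 10, mpmri: 345.0,
  mpmri_max: 397.0, mpmri_min: 293.0, mrigb: 800.0, mrigb_max: 920.0, mrigb_min: 680.0,
  palliative_terminal: 26000.0, psa_test: 30.0, trusgb: 247.0, trusgb_max: 284.0,
  trusgb_min: 210.0, tx_rp: 9000.0, tx_rt: 8500.0, tx_ww: 1500.0}
discount_rate: 0.035
life_table:
  ages: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20,
    21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38, 39, 40,
    41, 42, 43, 44, 45, 46, 47, 48, 49, 50, 51, 52, 53, 54, 55, 56, 57, 58, 59, 60,
    61, 62, 63, 64, 65, 66, 67, 68, 69, 70, 71, 72, 73, 74, 75, 76, 77, 78, 79, 80,
    81, 82, 83, 84, 85, 86, 87, 88, 89, 90, 91, 92, 93, 94, 95, 96, 97, 98, 99, 100]
  qx: [0.0005080411185640621, 0.0005089906523216836, 0.0005100505949670042, 0.0005112337843701242,
    0.0005125545510996643, 0.000514028891974494, 0.0005156746637926535, 0.0005175117995813716,
    0.0005195625499860856, 0.0005218517527206812, 0.000524407133339122, 0.000527259640968003,
    0.0005304438230639974, 0.0005339982437276847, 0.0005379659506370427, 0.000542394996245088,
    0.0005473390195475103, 0.000552857895452119, 0.0005590184596020453, 0.0005658953174108028,
    0.0005735717470859436, 0.000582140707548362, 0.0005917059634189537, 0.0006023833406521018,
    0.0006143021279658711, 0.0006276066409746095, 0.0006424579678757647, 0.0006590359177264249,
    0.0006775411947683718, 0.0006981978249629428, 0.0007212558639133615, 0.000746994418702851,
    0.0007757250199172949, 0.0008077953842765551, 0.0008435936129299604, 0.0008835528756210298,
    0.0009281566366490246, 0.0009779444849232766, 0.0010335186374749172, 0.0010955511936391327,
    0.001164792225832656, 0.0012420788025075957, 0.0013283450495576998, 0.001424633368295125,
    0.0015321069412018717, 0.0016520636711131464, 0.0017859517154252824, 0.0019353867944633674,
    0.00210217147242564, 0.0022883166304584757, 0.0024960653745501604, 0.0027279196461597044,
    0.0029866698309380935, 0.003275427690626609, 0.003597662975273752, 0.003957244107310909,
    0.0043584833656905575, 0.00480618703707858, 0.005305711041736605, 0.0058630225838035566,
    0.0064847684185938, 0.007178350372381903, 0.007952008791773935, 0.008814914638555882,
    0.009777270979762553, 0.010850424648856993, 0.01204698886879807, 0.013380977626840318,
    0.014867952568386467, 0.01652518312581719, 0.01837182050886721, 0.02042908604450344,
    0.022720474152482906, 0.025271969960767082, 0.02811228118204534, 0.03127308336380741,
    0.03478927695988021, 0.03869925381583572, 0.04304516957300053, 0.04787321712847248,
    0.05323389458788219, 0.05918225905421182, 0.06577815504601348, 0.07308640326625393,
    0.0811769317856138, 0.09012482740730954, 0.10001028000933954, 0.11091838701257972,
    0.12293877885036175, 0.13616501954749183, 0.15069372949885607, 0.166623370673059,
    0.18405262837087133, 0.2030783192334974, 0.2237927536589973, 0.24628048379801315,
    0.2706143779838356, 0.2968509814219812, 0.3250251542894529, 0.3551440254493279,
    1.0]
natural_history:
  onset_hazard:
  - {age_from: 35.0, age_to: 45.0, rate: 0.0008}
  - {age_from: 45.0, age_to: 55.0, rate: 0.0028}
  - {age_from: 55.0, age_to: 65.0, rate: 0.0052}
  - {age_from: 65.0, age_to: 75.0, rate: 0.006}
  - {age_from: 75.0, age_to: 100.0, rate: 0.0044}
  onset_state_probs: {T1.Glt7.LR: 1.0}
  transition_rates:
    T1.Geq7.D: {clinical_dx: 0.45, grade_advance: 0.11, metastasize: 0.0, t_advance: 0.16}
    T1.Geq7.LR: {clinical_dx: 0.025, grade_advance: 0.11, metastasize: 0.012, t_advance: 0.16}
    T1.Ggt7.D: {clinical_dx: 0.45, grade_advance: 0.0, metastasize: 0.0, t_advance: 0.16}
    T1.Ggt7.LR: {clinical_dx: 0.025, grade_advance: 0.0, metastasize: 0.02, t_advance: 0.16}
    T1.Glt7.D: {clinical_dx: 0.45, grade_advance: 0.09, metastasize: 0.0, t_advance: 0.16}
    T1.Glt7.LR: {clinical_dx: 0.025, grade_advance: 0.09, metastasize: 0.008, t_advance: 0.16}
    T2.Geq7.D: {clinical_dx: 0.45, grade_advance: 0.11, metastasize: 0.0, t_advance: 0.22}
    T2.Geq7.LR: {clinical_dx: 0.07, grade_advance: 0.11, metastasize: 0.0525, t_advance: 0.22}
    T2.Ggt7.D: {clinical_dx: 0.45, grade_advance: 0.0, metastasize: 0.0, t_advance: 0.22}
    T2.Ggt7.LR: {clinical_dx: 0.07, grade_advance: 0.0, metastasize: 0.0875, t_advance: 0.22}
    T2.Glt7.D: {clinical_dx: 0.45, grade_advance: 0.09, metastasize: 0.0, t_advance: 0.22}
    T2.Glt7.LR: {clinical_dx: 0.07, grade_advance: 0.09, metastasize: 0.035, t_advance: 0.22}
    T3.Geq7.D: {clinical_dx: 0.45, grade_advance: 0.11, metastasize: 0.0, t_advance: 0.0}
    T3.Geq7.LR: {clinical_dx: 0.18, grade_advance: 0.11, metastasize: 0.18, t_advance: 0.0}
    T3.Ggt7.D: {clinical_dx: 0.45, grade_advance: 0.0, metastasize: 0.0, t_advance: 0.0}
    T3.Ggt7.LR: {clinical_dx: 0.18, grade_advance: 0.0, metastasize: 0.3, t_advance: 0.0}
    T3.Glt7.D: {clinical_dx: 0.45, grade_advance: 0.09, metastasize: 0.0, t_advance: 0.0}
    T3.Glt7.LR: {clinical_dx: 0.18, grade_advance: 0.09, metastasize: 0.12, t_advance: 0.0}
protocol: {attendance: 0.8, biopsy_compliance: 0.9, interval: 3.0, persistent_attendance: false,
  psa_threshold: 3.0, start_age: 55.0, stop_age: 64.0}
survival:
  age_band_factors: {a60_69: 1.0, a70p: 1.1, lt60: 0.9}
  baseline:
    D.HGC: {death_prob: 0.92, scale: 2.6, shape: 1.1}
    D.LGC: {death_prob: 0.85, scale: 3.0, shape: 1.1}
    LR.HGC: {death_prob: 0.45, scale: 9.0, shape: 1.2}
    LR.LGC: {death_prob: 0.12, scale: 14.0, shape: 1.3}
  cure: {baseline: 0.0, max: 0.8, slope: 0.22}
  rr_rp: 0.56
  rr_rt: 0.56
tests:
  hgc_grades: [Geq7, Ggt7]
  misclass_mrigb: 0.087
  misclass_trusgb: 0.363
  mpmri_pos_rate_nocancer: 0.48
  mpmri_sens_hgc: 0.94
  mpmri_sens_lgc: 0.74
  mrigb_sens_hgc: 0.91
  mrigb_sens_lgc: 0.44
  ppv_classical: 0.45
  ppv_mri: 0.4
  psa_sens_by_state: {T1.Geq7.D: 0.95, T1.Geq7.LR: 0.45, T1.Ggt7.D: 0.95, T1.Ggt7.LR: 0.45,
    T1.Glt7.D: 0.95, T1.Glt7.LR: 0.45, T2.Geq7.D: 0.95, T2.Geq7.LR: 0.72, T2.Ggt7.D: 0.95,
    T2.Ggt7.LR: 0.72, T2.Glt7.D: 0.95, T2.Glt7.LR: 0.72, T3.Geq7.D: 0.95, T3.Geq7.LR: 0.9,
    T3.Ggt7.D: 0.95, T3.Ggt7.LR: 0.9, T3.Glt7.D: 0.95, T3.Glt7.LR: 0.9}
  trusgb_sens: 0.9
treatment:
  a60_69.T1.HGC: {RP: 0.45, RT: 0.4, WW: 0.15}
  a60_69.T1.LGC: {RP: 0.1, RT: 0.05, WW: 0.85}
  a60_69.T2.HGC: {RP: 0.45, RT: 0.4, WW: 0.15}
  a60_69.T2.LGC: {RP: 0.1, RT: 0.05, WW: 0.85}
  a60_69.T3.HGC: {RP: 0.45, RT: 0.4, WW: 0.15}
  a60_69.T3.LGC: {RP: 0.1, RT: 0.05, WW: 0.85}
  a70p.T1.HGC: {RP: 0.15, RT: 0.45, WW: 0.4}
  a70p.T1.LGC: {RP: 0.02, RT: 0.08, WW: 0.9}
  a70p.T2.HGC: {RP: 0.15, RT: 0.45, WW: 0.4}
  a70p.T2.LGC: {RP: 0.02, RT: 0.08, WW: 0.9}
  a70p.T3.HGC: {RP: 0.15, RT: 0.45, WW: 0.4}
  a70p.T3.LGC: {RP: 0.02, RT: 0.08, WW: 0.9}
  lt60.T1.HGC: {RP: 0.55, RT: 0.35, WW: 0.1}
  lt60.T1.LGC: {RP: 0.15, RT: 0.05, WW: 0.8}
  lt60.T2.HGC: {RP: 0.55, RT: 0.35, WW: 0.1}
  lt60.T2.LGC: {RP: 0.15, RT: 0.05, WW: 0.8}
  lt60.T3.HGC: {RP: 0.55, RT: 0.35, WW: 0.1}
  lt60.T3.LGC: {RP: 0.15, RT: 0.05, WW: 0.8}
utilities:
  entries:
    biopsy_mrigb: {duration: 0.057692307692307696, utility: 0.95}
    biopsy_trusgb: {duration: 0.057692307692307696, utility: 0.9}
    diagnosis: {duration: 0.25, utility: 0.85}
    palliative: {duration: 2.5, utility: 0.6}
    post_treatment: {duration: 8.0, utility: 0.95}
    screening_visit: {duration: 0.019230769230769232, utility: 0.99}
    terminal: {duration: 0.5, utility: 0.4}
    tx_rp: {duration: 0.5, utility: 0.67}
    tx_rt: {duration: 0.5, utility: 0.73}
    tx_ww: {duration: 5.0, utility: 0.97}
  mrigb_half_loss: true
  negative_biopsy_disutility: true
wtp: 20000.0
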