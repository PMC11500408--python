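# metalff Lennard-Jones library for metal ions (fixture entries)
# Representative 12-6 parameters in the style of the named families
# (merz/zhang: ion 12-6 sets; uff: universal force field atoms).
# columns: symbol  formal_charge  source  rmin_half_A  eps_kcal
Zn  2  merz   1.395  0.00330600
Fe  2  merz   1.457  0.00490301
Co  2  merz   1.404  0.00350219
Pd  2  merz   1.303  0.00143622
Ga  3  merz   1.545  0.01205473
Zn  2  zhang  1.245  0.00112300
Fe  2  zhang  1.275  0.00160860
Co  2  zhang  1.299  0.00191142
Pd  2  zhang  1.303  0.00201230
Ga  3  zhang  1.335  0.00261320
Zn  2  uff    1.3815 0.124
Fe  2  uff    1.4560 0.013
Co  2  uff    1.4360 0.014
Pd  2  uff    1.4495 0.048
Ga  3  uff    2.1915 0.415
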