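# sugarcdl conformation-dependent sugar restraint targets -- SYNTHETIC reference set, v1.
# This file is a synthetic reference dictionary: entries whose values are stated in the
# published running text are transcribed exactly (terminal C5'-O5' = 1.421 A; terminal vs
# non-terminal C4'-C5'-O5' for chi anti / gamma gauche+ = 111.5 / 110.6 deg; terminal C3'-O3'
# range 1.414-1.422 A; glycosidic cosine amplitudes spanning 0.007-0.018 A; tau_m slopes
# spanning -0.241..-0.088 deg/deg, all negative). The remaining group values are filled in
# from standard nucleoside geometry and are NOT transcriptions of the published tables.
# Forms: fixed (value); linear_tau (value = a*tau_m + b, tau_m in deg); periodic_chi
# (value = a*cos(2*chi + b) + c, chi in deg; the 180-deg period resolves the printed
# a*cos(chi/2 + b) formula, treated as a typo); grid_chi (dense-curve lookup in
# chi_angle_curves_synthetic.csv keyed by parameter+base).
# Wildcard '*' = not conditioned on that key. n = sample size of the group.
parameter,kind,sugar,base,pucker,chi,gamma,terminal,form,value,a,b,c,sigma,n
C1'-C2',bond,*,*,*,*,*,*,fixed,1.528,,,,0.010,432
C2'-C3',bond,*,*,*,*,*,*,fixed,1.525,,,,0.011,432
C2'-O2',bond,ribose,*,*,*,*,*,fixed,1.412,,,,0.009,214
C4'-O4',bond,ribose,*,*,*,*,*,fixed,1.453,,,,0.008,214
C4'-O4',bond,deoxyribose,*,*,*,*,*,fixed,1.446,,,,0.009,218
C3'-C4',bond,*,*,C2'-endo,*,*,*,fixed,1.528,,,,0.009,195
C3'-C4',bond,*,*,C3'-endo,*,*,*,fixed,1.518,,,,0.008,194
C3'-C4',bond,*,*,Other,*,*,*,fixed,1.523,,,,0.010,43
C4'-C5',bond,*,*,*,*,gauche+,*,fixed,1.508,,,,0.007,268
C4'-C5',bond,*,*,*,*,trans,*,fixed,1.509,,,,0.008,86
C4'-C5',bond,*,*,*,*,gauche-,*,fixed,1.514,,,,0.008,56
C1'-N,bond,*,purine,*,*,*,*,periodic_chi,,0.012,0.0,1.460,0.009,181
C1'-N,bond,*,pyrimidine,*,*,*,*,periodic_chi,,0.018,0.0,1.474,0.010,251
O4'-C1',bond,ribose,*,*,*,*,*,periodic_chi,,0.007,180.0,1.414,0.009,214
O4'-C1',bond,deoxyribose,*,*,*,*,*,periodic_chi,,0.009,180.0,1.418,0.010,218
C3'-O3',bond,ribose,*,*,*,*,yes,fixed,1.422,,,,0.010,193
C3'-O3',bond,deoxyribose,*,*,*,*,yes,fixed,1.414,,,,0.010,158
C5'-O5',bond,*,*,*,*,*,yes,fixed,1.421,,,,0.010,291
C1'-C2'-C3',angle,ribose,*,C3'-endo,*,*,*,linear_tau,,-0.130,106.24,,0.6,118
C1'-C2'-C3',angle,ribose,*,C2'-endo,*,*,*,linear_tau,,-0.150,107.20,,0.6,75
C1'-C2'-C3',angle,ribose,*,Other,*,*,*,linear_tau,,-0.160,107.88,,0.6,21
C1'-C2'-C3',angle,deoxyribose,*,C3'-endo,*,*,*,linear_tau,,-0.150,107.60,,0.6,76
C1'-C2'-C3',angle,deoxyribose,*,C2'-endo,*,*,*,linear_tau,,-0.120,106.86,,0.6,120
C1'-C2'-C3',angle,deoxyribose,*,Other,*,*,*,linear_tau,,-0.170,108.56,,0.6,22
C2'-C3'-C4',angle,ribose,*,C3'-endo,*,*,*,linear_tau,,-0.160,108.68,,0.6,118
C2'-C3'-C4',angle,ribose,*,C2'-endo,*,*,*,linear_tau,,-0.180,109.54,,0.6,75
C2'-C3'-C4',angle,ribose,*,Other,*,*,*,linear_tau,,-0.190,110.22,,0.6,21
C2'-C3'-C4',angle,deoxyribose,*,C3'-endo,*,*,*,linear_tau,,-0.170,109.36,,0.6,76
C2'-C3'-C4',angle,deoxyribose,*,C2'-endo,*,*,*,linear_tau,,-0.150,108.90,,0.6,120
C2'-C3'-C4',angle,deoxyribose,*,Other,*,*,*,linear_tau,,-0.200,110.90,,0.6,22
C3'-C4'-O4',angle,ribose,*,C3'-endo,*,*,*,linear_tau,,-0.200,111.80,,0.6,118
C3'-C4'-O4',angle,ribose,*,C2'-endo,*,*,*,linear_tau,,-0.180,112.44,,0.6,75
C3'-C4'-O4',angle,ribose,*,Other,*,*,*,fixed,104.9,,,,1.2,21
C3'-C4'-O4',angle,deoxyribose,*,C3'-endo,*,*,*,linear_tau,,-0.210,112.58,,0.6,76
C3'-C4'-O4',angle,deoxyribose,*,C2'-endo,*,*,*,linear_tau,,-0.190,113.12,,0.6,120
C3'-C4'-O4',angle,deoxyribose,*,Other,*,*,*,linear_tau,,-0.160,111.38,,0.6,22
C4'-O4'-C1',angle,ribose,*,C3'-endo,*,*,*,linear_tau,,-0.241,118.86,,0.6,118
C4'-O4'-C1',angle,ribose,*,C2'-endo,*,*,*,linear_tau,,-0.220,118.26,,0.6,75
C4'-O4'-C1',angle,ribose,*,Other,*,*,*,linear_tau,,-0.190,117.42,,0.6,21
C4'-O4'-C1',angle,deoxyribose,*,C3'-endo,*,*,*,linear_tau,,-0.230,118.64,,0.6,76
C4'-O4'-C1',angle,deoxyribose,*,C2'-endo,*,*,*,linear_tau,,-0.215,118.17,,0.6,120
C4'-O4'-C1',angle,deoxyribose,*,Other,*,*,*,linear_tau,,-0.185,117.33,,0.6,22
O4'-C1'-C2',angle,ribose,*,C3'-endo,*,*,*,linear_tau,,-0.150,111.70,,0.6,118
O4'-C1'-C2',angle,ribose,*,C2'-endo,*,*,*,linear_tau,,-0.160,112.28,,0.6,75
O4'-C1'-C2',angle,ribose,*,Other,*,*,*,linear_tau,,-0.170,112.86,,0.6,21
O4'-C1'-C2',angle,deoxyribose,*,C3'-endo,*,*,*,linear_tau,,-0.120,110.46,,0.6,76
O4'-C1'-C2',angle,deoxyribose,*,C2'-endo,*,*,*,linear_tau,,-0.088,109.44,,0.6,120
O4'-C1'-C2',angle,deoxyribose,*,Other,*,*,*,linear_tau,,-0.175,112.95,,0.6,22
C1'-C2'-O2',angle,ribose,*,C3'-endo,anti,*,*,fixed,110.4,,,,1.2,100
C1'-C2'-O2',angle,ribose,*,C3'-endo,syn,*,*,fixed,111.6,,,,1.4,18
C1'-C2'-O2',angle,ribose,*,C2'-endo,anti,*,*,fixed,111.8,,,,1.3,64
C1'-C2'-O2',angle,ribose,*,C2'-endo,syn,*,*,fixed,113.0,,,,1.5,11
C1'-C2'-O2',angle,ribose,*,Other,anti,*,*,fixed,111.0,,,,1.4,18
C1'-C2'-O2',angle,ribose,*,Other,syn,*,*,fixed,112.2,,,,1.6,6
C3'-C2'-O2',angle,ribose,*,C3'-endo,anti,*,*,fixed,113.6,,,,1.3,100
C3'-C2'-O2',angle,ribose,*,C3'-endo,syn,*,*,fixed,112.4,,,,1.5,18
C3'-C2'-O2',angle,ribose,*,C2'-endo,anti,*,*,fixed,109.9,,,,1.4,64
C3'-C2'-O2',angle,ribose,*,C2'-endo,syn,*,*,fixed,109.0,,,,1.6,11
C3'-C2'-O2',angle,ribose,*,Other,anti,*,*,fixed,111.8,,,,1.5,18
C3'-C2'-O2',angle,ribose,*,Other,syn,*,*,fixed,111.0,,,,1.6,6
C2'-C3'-O3',angle,*,*,C3'-endo,anti,*,no,fixed,113.5,,,,1.3,165
C2'-C3'-O3',angle,*,*,C3'-endo,syn,*,no,fixed,112.8,,,,1.5,29
C2'-C3'-O3',angle,*,*,C2'-endo,anti,*,no,fixed,109.6,,,,1.3,166
C2'-C3'-O3',angle,*,*,C2'-endo,syn,*,no,fixed,109.0,,,,1.5,29
C2'-C3'-O3',angle,*,*,Other,anti,*,no,fixed,111.4,,,,1.4,37
C2'-C3'-O3',angle,*,*,Other,syn,*,no,fixed,110.8,,,,1.6,6
C4'-C3'-O3',angle,*,*,C3'-endo,anti,*,no,fixed,113.2,,,,1.2,165
C4'-C3'-O3',angle,*,*,C3'-endo,syn,*,no,fixed,112.5,,,,1.4,29
C4'-C3'-O3',angle,*,*,C2'-endo,anti,*,no,fixed,110.3,,,,1.2,166
C4'-C3'-O3',angle,*,*,C2'-endo,syn,*,no,fixed,109.8,,,,1.4,29
C4'-C3'-O3',angle,*,*,Other,anti,*,no,fixed,111.6,,,,1.3,37
C4'-C3'-O3',angle,*,*,Other,syn,*,no,fixed,111.1,,,,1.5,6
C3'-C4'-C5',angle,*,*,*,*,gauche+,*,fixed,115.7,,,,1.2,268
C3'-C4'-C5',angle,*,*,*,*,trans,*,fixed,114.8,,,,1.3,86
C3'-C4'-C5',angle,*,*,*,*,gauche-,*,fixed,116.8,,,,1.4,56
C5'-C4'-O4',angle,*,*,*,*,gauche+,*,fixed,109.3,,,,1.1,268
C5'-C4'-O4',angle,*,*,*,*,trans,*,fixed,109.9,,,,1.2,86
C5'-C4'-O4',angle,*,*,*,*,gauche-,*,fixed,108.6,,,,1.3,56
C4'-C5'-O5',angle,*,*,*,anti,gauche+,no,fixed,110.6,,,,1.4,232
C4'-C5'-O5',angle,*,*,*,anti,trans,no,fixed,110.2,,,,1.5,82
C4'-C5'-O5',angle,*,*,*,anti,gauche-,no,fixed,111.9,,,,1.6,46
C4'-C5'-O5',angle,*,*,*,syn,gauche+,no,fixed,111.3,,,,1.5,36
C4'-C5'-O5',angle,*,*,*,syn,trans,no,fixed,111.0,,,,1.6,13
C4'-C5'-O5',angle,*,*,*,syn,gauche-,no,fixed,112.8,,,,1.7,10
N-C1'-C2',angle,*,purine,*,*,*,*,grid_chi,,,,,1.3,181
N-C1'-C2',angle,*,pyrimidine,*,*,*,*,grid_chi,,,,,1.3,251
N-C1'-O4',angle,*,purine,*,*,*,*,grid_chi,,,,,1.1,181
N-C1'-O4',angle,*,pyrimidine,*,*,*,*,grid_chi,,,,,1.1,251
C1'-N-C2/C4,angle,*,purine,*,*,*,*,grid_chi,,,,,1.4,181
C1'-N-C2/C4,angle,*,pyrimidine,*,*,*,*,grid_chi,,,,,1.4,251
C1'-N-C6/C8,angle,*,purine,*,*,*,*,grid_chi,,,,,1.4,181
C1'-N-C6/C8,angle,*,pyrimidine,*,*,*,*,grid_chi,,,,,1.4,251
C2'-C3'-O3',angle,*,*,C3'-endo,*,*,yes,fixed,113.3,,,,1.2,150
C2'-C3'-O3',angle,*,*,C2'-endo,*,*,yes,fixed,109.3,,,,1.2,163
C2'-C3'-O3',angle,*,*,Other,*,*,yes,fixed,111.2,,,,1.3,38
C4'-C3'-O3',angle,*,*,C3'-endo,*,*,yes,fixed,113.0,,,,1.1,150
C4'-C3'-O3',angle,*,*,C2'-endo,*,*,yes,fixed,110.0,,,,1.1,163
C4'-C3'-O3',angle,*,*,Other,*,*,yes,fixed,111.4,,,,1.2,38
C4'-C5'-O5',angle,*,*,*,anti,gauche+,yes,fixed,111.5,,,,1.4,186
C4'-C5'-O5',angle,*,*,*,anti,trans,yes,fixed,110.5,,,,1.5,61
C4'-C5'-O5',angle,*,*,*,anti,gauche-,yes,fixed,112.2,,,,1.5,22
C4'-C5'-O5',angle,*,*,*,syn,gauche+,yes,fixed,111.7,,,,1.5,14
C4'-C5'-O5',angle,*,*,*,syn,trans,yes,fixed,111.3,,,,1.6,5
C4'-C5'-O5',angle,*,*,*,syn,gauche-,yes,fixed,113.1,,,,1.7,3
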