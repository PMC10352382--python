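study,sex,cohort,n_mz,n_dz,r_mz,r_dz,r_parents
Heath et al. (1985),male,1915-1939,259,313,0.86,0.77,0.86
Heath et al. (1985),female,1915-1939,405,425,0.89,0.75,0.86
Heath et al. (1985),male,1940-1949,253,284,0.82,0.48,0.72
Heath et al. (1985),female,1940-1949,342,400,0.85,0.68,0.72
Heath et al. (1985),male,1950-1960,370,463,0.85,0.47,0.73
Heath et al. (1985),female,1950-1960,518,576,0.89,0.66,0.73
Lykken et al. (1990),male,1936-1955,433,632,0.64,0.44,0.55
Lykken et al. (1990),female,1936-1955,392,571,0.66,0.50,0.55
Baker et al. (1996),male,1893-1950,216,94,0.70,0.53,0.426
Baker et al. (1996),female,1893-1950,520,299,0.77,0.55,0.426
Baker et al. (1996),male,1951-1965,226,161,0.74,0.47,0.426
Baker et al. (1996),female,1951-1965,479,290,0.75,0.49,0.426
Bingley et al. (2005),male,1925-1977,2185,3534,0.62,0.444,0.392
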