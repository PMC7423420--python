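label,lat,lon,population
Hokkaido,43.06417,141.34694,5286
Aomori,40.82444,140.74,1263
Iwate,39.70361,141.1525,1241
Miyagi,38.26889,140.87194,2316
Akita,39.71861,140.1025,981
Yamagata,38.24056,140.36333,1090
Fukushima,37.75,140.46778,1864
Ibaraki,36.34139,140.44667,2877
Tochigi,36.56583,139.88361,1946
Gunma,36.39111,139.06083,1952
Saitama,35.85694,139.64889,7330
Chiba,35.60472,140.12333,6255
Tokyo,35.68944,139.69167,13822
Kanagawa,35.44778,139.6425,9177
Niigata,37.90222,139.02361,2246
Toyama,36.69528,137.21139,1050
Ishikawa,36.59444,136.62556,1143
Fukui,36.06528,136.22194,774
Yamanashi,35.66389,138.56833,817
Nagano,36.65139,138.18111,2063
Gifu,35.39111,136.72222,1997
Shizuoka,34.97694,138.38306,3659
Aichi,35.18028,136.90667,7537
Mie,34.73028,136.50861,1791
Shiga,35.00444,135.86833,1412
Kyoto,35.02139,135.75556,2591
Osaka,34.68639,135.52,8813
Hyogo,34.69139,135.18306,5484
Nara,34.68528,135.83278,1339
Wakayama,34.22611,135.1675,935
Tottori,35.50361,134.23833,560
Shimane,35.47222,133.05056,680
Okayama,34.66167,133.935,1898
Hiroshima,34.39639,132.45944,2817
Yamaguchi,34.18583,131.47139,1370
Tokushima,34.06583,134.55944,736
Kagawa,34.34028,134.04333,962
Ehime,33.84167,132.76611,1352
Kochi,33.55972,133.53111,706
Fukuoka,33.60639,130.41806,5107
Saga,33.24944,130.29889,819
Nagasaki,32.74472,129.87361,1341
Kumamoto,32.78972,130.74167,1757
Oita,33.23806,131.6125,1144
Miyazaki,31.91111,131.42389,1081
Kagoshima,31.56028,130.55806,1614
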