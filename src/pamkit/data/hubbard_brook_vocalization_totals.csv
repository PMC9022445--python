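common_name,code,taxon_class,total_2016,total_2018
Red-eyed Vireo,REVI,bird,46817,26998
Black-throated Blue Warbler,BTBW,bird,6890,4316
Black-throated Green Warbler,BTNW,bird,5399,4096
Ovenbird,OVEN,bird,3781,4192
Hermit Thrush,HETH,bird,4051,1824
Red-breasted Nuthatch,RBNU,bird,32,2804
American Redstart,AMRE,bird,2278,233
Blue-headed Vireo,BHVI,bird,427,1995
Swainson's Thrush,SWTH,bird,880,1313
Red Squirrel,RESQ,mammal,,910
Yellow-rumped Warbler,YRWA,bird,48,847
Winter Wren,WIWR,bird,514,215
Golden-crowned Kinglet,GCKI,bird,511,172
Black-capped Chickadee,BCCH,bird,92,561
Yellow-bellied Sapsucker,YBSA,bird,299,304
Eastern Wood-Pewee,EWPE,bird,0,542
Black-and-white Warbler,BAWW,bird,73,459
Scarlet Tanager,SCTA,bird,48,338
Blue Jay,BLJA,bird,62,296
Magnolia Warbler,MAWA,bird,0,328
White-breasted Nuthatch,WBNU,bird,0,315
Blackburnian Warbler,BLWA,bird,7,307
Dark-eyed Junco,DEJU,bird,0,249
Hairy Woodpecker,HAWO,bird,68,177
American Robin,AMRO,bird,218,18
Pine Siskin,PISI,bird,0,220
Brown Creeper,BRCR,bird,87,106
Cape May Warbler,CMWA,bird,34,159
Rose-breasted Grosbeak,RBGR,bird,56,100
Red Crossbill,RECR,bird,0,92
Louisiana Waterthrush,LOWA,bird,64,0
Purple Finch,PUFI,bird,24,39
Downy Woodpecker,DOWO,bird,48,1
Veery,VEER,bird,0,31
Wood Thrush,WOTH,bird,0,26
Eastern Chipmunk,EACH,mammal,,24
Ruby-throated Hummingbird,RTHU,bird,21,1
Pileated Woodpecker,PIWO,bird,10,11
Alder Flycatcher,ALFL,bird,0,18
American Goldfinch,AMGO,bird,0,14
Cedar Waxwing,CEDW,bird,0,13
Blackpoll Warbler,BLPW,bird,0,8
Canada Warbler,CAWA,bird,0,5
Pine Warbler,PIWA,bird,0,4
Common Loon,COLO,bird,3,0
Great-crested Flycatcher,GCFL,bird,2,0
Northern Parula,NOPA,bird,0,2
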