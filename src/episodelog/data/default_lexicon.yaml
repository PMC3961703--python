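# Default query lexicons.
#
# The 63-category keyword taxonomy is a transparent stand-in for a
# commercial search engine's proprietary topical classifier: category
# names include the topics analysed downstream (nutrition, business,
# commerce, adult, ...) but the list itself is this package's own.
# Matching is case-insensitive on word boundaries; multiword keywords
# match as contiguous token sequences. A query may match several
# categories ("purchase flight tickets" -> tourism + commerce).
categories:
  nutrition: [nutrition, calories, diet, vitamins]
  business: [business, marketing, startup, wholesale]
  commerce: [purchase, buy, tickets, checkout, coupon]
  adult: [adult, porn, xxx, nsfw]
  tourism: [flight, vacation, tourism, sightseeing]
  vehicles: [car, truck, sedan, tire]
  books: [book, novel, paperback, bestseller]
  clothes_and_shoes: [shoes, dress, jeans, sneakers]
  celebrities: [celebrity, gossip, hollywood, paparazzi]
  consumer_electronics: [laptop, headphones, tablet, camera]
  events: [concert, festival, parade, expo]
  finance: [stocks, loan, mortgage, invest]
  flight_status: [flight status, flight tracker, flight delayed]
  health: [health, doctor, symptoms, medication, pharmacy]
  video_games: [xbox, playstation, videogame, minecraft]
  weather: [weather, forecast, rain, temperature]
  news: [news, headlines, breaking]
  sports: [football, basketball, baseball, playoffs]
  music: [music, song, lyrics, album]
  movies: [movie, trailer, cinema, showtimes]
  television: [tv, episode, sitcom, channel]
  education: [university, homework, tuition, syllabus]
  jobs: [job, resume, salary, hiring]
  real_estate: [realtor, apartment, rent, condo]
  pets: [dog, cat, puppy, veterinarian]
  gardening: [garden, seeds, compost, lawn]
  parenting: [baby, toddler, diaper, stroller]
  relationships: [dating, marriage, divorce, anniversary]
  astrology: [horoscope, zodiac, astrology, tarot]
  religion: [church, bible, prayer, sermon]
  law: [lawyer, lawsuit, attorney, verdict]
  government: [passport, visa, irs, dmv]
  politics: [election, senator, congress, ballot]
  science: [physics, chemistry, biology, astronomy]
  technology: [robotics, nanotech, innovation, prototype]
  software: [download, windows, linux, freeware]
  hardware: [motherboard, cpu, ssd, router]
  mobile_phones: [iphone, android, smartphone, ringtone]
  photography: [photography, dslr, tripod, exposure]
  art: [painting, museum, sculpture, gallery]
  crafts: [knitting, crochet, scrapbook, quilting]
  home_improvement: [plumbing, renovation, drywall, insulation]
  furniture: [sofa, mattress, bookshelf, recliner]
  appliances: [refrigerator, dishwasher, microwave, dryer]
  beauty: [makeup, lipstick, skincare, mascara]
  fitness: [gym, workout, treadmill, yoga]
  outdoors: [hiking, camping, kayak, trail]
  hunting_fishing: [fishing, hunting, bait, decoy]
  hotels: [hotel, motel, resort, hostel]
  restaurants: [restaurant, menu, diner, takeout]
  local_services: [plumber, electrician, locksmith, handyman]
  maps_directions: [directions, map, route, mileage]
  reference: [encyclopedia, wiki, definition, thesaurus]
  images: [wallpaper, clipart, images, screensaver]
  social_media: [facebook, twitter, instagram, hashtag]
  email: [email, inbox, gmail, attachment]
  toys: [lego, toys, dollhouse, playset]
  board_games: [chess, monopoly, sudoku, crossword]
  gambling: [casino, poker, lottery, blackjack]
  automotive_services: [mechanic, carwash, muffler, oil change]
  insurance: [insurance, premium, deductible, copay]
  taxes: [taxes, refund, deduction, withholding]
  recipes: [recipe, baking, casserole, marinade]

# Mood-stabilizing-drug query detection. "lithium" counts only when none
# of the exclusion terms co-occur in the same query (battery/metal senses).
drug_lexicon:
  msd_names:
    - eskalith
    - lithobid
    - lithonate
    - lithotabs
    - valproic acid
    - divalproex
    - valproate
    - depakote
    - depakene
  stabilizer_stems: ["mood stabiliz"]
  lithium_term: lithium
  lithium_exclusions: [battery, batteries, ion, aa, charger, mine, mining, grease, nirvana]

mood_terms:
  disorder_terms: [mood disorder, mood disorders, depression, mania, manic, bipolar]
  first_person_markers: [i, i'm, my]
  other_person_markers:
    - my wife
    - my husband
    - my spouse
    - my son
    - my daughter
    - my boyfriend
    - my girlfriend
  comorbid_terms: [migraine, migraines, seizure, seizures]
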